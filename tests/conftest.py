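"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mexnet import MutationMatrix
from mexnet.association import ContingencyTable


@pytest.fixture
def toy_maf(tmp_path):
    """Six-record MAF over 3 genes x 3 samples with mixed variant classes.

    Qualifying hits by hand: TP53 in S1 (twice, collapses) and S2;
    KRAS in S2 (Nonsense) and S3 (Stop_Lost); EGFR only Silent -> absent.
    """
    records = [
        ("TP53", "S1", "Missense_Mutation"),
        ("TP53", "S1", "Missense_Mutation"),
        ("TP53", "S2", "missense_mutation"),
        ("KRAS", "S2", "Nonsense_Mutation"),
        ("KRAS", "S3", "Stop_Lost"),
        ("EGFR", "S3", "Silent"),
    ]
    path = tmp_path / "toy.maf"
    lines = ["Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification"]
    lines += ["\t".join(r) for r in records]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_pathway_file(tmp_path):
    """Ten-edge toy pathway; hand count: 12 nodes, 10 edges."""
    edges = [
        ("KRAS", "RAF1"), ("RAF1", "MAP2K1"), ("MAP2K1", "MAPK1"),
        ("KRAS", "PIK3CA"), ("PIK3CA", "AKT1"), ("AKT1", "MTOR"),
        ("EGFR", "KRAS"), ("ERBB2", "EGFR"), ("BRCA2", "FANCA"),
        ("FANCA", "FANCD2"),
    ]
    path = tmp_path / "toy_pathway.tsv"
    path.write_text("# toy pathway\n" + "\n".join(f"{a}\t{b}" for a, b in edges) + "\n")
    return path


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"S{j}" for j in range(20)]
    return MutationMatrix(genes, samples, (rng.random((6, 20)) < 0.3).astype(int))


# ---------------------------------------------------------------------------
# independent oracles


def fisher_oracle(table: ContingencyTable) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(table') over all tables with the observed margins whose point
    probability does not exceed the observed one (probability method), the
    tie decided on exact integer numerators. Accumulates per-table float
    probabilities, so it shares no code path with the implementation.
    """
    from fractions import Fraction

    a, b, c, d = table.both, table.a_only, table.b_only, table.neither
    n = a + b + c + d
    r = a + b  # gene-A-mutated margin
    k = a + c  # gene-B-mutated margin
    denom = math.comb(n, k)
    num_obs = math.comb(r, a) * math.comb(n - r, k - a)
    total = Fraction(0)
    for x in range(max(0, r + k - n), min(r, k) + 1):
        num_x = math.comb(r, x) * math.comb(n - r, k - x)
        if num_x <= num_obs:
            total += Fraction(num_x, denom)
    return min(float(total), 1.0)


def modularity_oracle(graph, modules) -> float:
    """Weighted Newman modularity, written independently for tests."""
    two_w = 2.0 * sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    if two_w == 0:
        return 0.0
    member = {g: i for i, mod in enumerate(modules) for g in mod}
    q = 0.0
    strength = {v: 0.0 for v in graph.nodes}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        strength[u] += w
        strength[v] += w
        if member[u] == member[v]:
            q += 2.0 * w / two_w
    for mod in modules:
        s = sum(strength[v] for v in mod)
        q -= (s / two_w) ** 2
    return q


def set_partitions(items):
    """Enumerate every set partition of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] | {first}] + partition[i + 1 :]
        yield partition + [{first}]
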