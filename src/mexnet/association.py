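"""Pairwise gene-gene mutual-exclusivity testing (workflow step 1).

For every pair of sufficiently mutated genes, the 2x2 contingency table of
mutation status across samples is tested with a two-sided Fisher exact test
and a univariate logistic regression of one gene's status on the other. A
pair is flagged mutually exclusive when the corrected odds ratio and the
logistic slope are both negative-direction (OR < 1, coef < 0) and the
Fisher p-value falls below the keep threshold (default 0.001).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import MutationMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "AssociationRecord",
    "contingency",
    "fisher_exact",
    "glm_logistic",
    "pairwise_associations",
]

#: cap on |logistic slope| under complete separation / zero cells
GLM_COEF_CAP = 20.0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 layout of joint mutation status over all samples."""

    both: int
    a_only: int
    b_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.a_only, self.b_only, self.neither) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    def swapped(self) -> "ContingencyTable":
        """The same table with the roles of gene A and gene B exchanged."""
        return ContingencyTable(self.both, self.b_only, self.a_only, self.neither)

    @property
    def degenerate(self) -> bool:
        """True when a margin is zero (a gene mutated in no or all samples)."""
        return (
            self.both + self.a_only == 0
            or self.b_only + self.neither == 0
            or self.both + self.b_only == 0
            or self.a_only + self.neither == 0
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One gene pair's tests; genes stored in lexicographic order."""

    gene_a: str
    gene_b: str
    table: ContingencyTable
    fisher_p: float
    odds_ratio: float
    glm_coef: float
    glm_p: float
    mutually_exclusive: bool


def contingency(matrix: MutationMatrix, gene_a: str, gene_b: str) -> ContingencyTable:
    """Cross-tabulate mutation status of two genes over all samples."""
    a = matrix.row(gene_a).astype(bool)
    b = matrix.row(gene_b).astype(bool)
    return ContingencyTable(
        both=int((a & b).sum()),
        a_only=int((a & ~b).sum()),
        b_only=int((~a & b).sum()),
        neither=int((~a & ~b).sum()),
    )


def corrected_odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio with the Haldane-Anscombe 0.5 correction.

    The correction (adding 0.5 to every cell) is applied only when some cell
    is zero, so that perfectly exclusive pairs yield a finite OR < 1.
    """
    a, b, c, d = table.both, table.a_only, table.b_only, table.neither
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table (probability method).

    Returns ``(p, odds_ratio)`` where p sums the hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's, and the odds ratio carries the
    Haldane-Anscombe correction for zero cells. A degenerate margin (a gene
    mutated in zero or all samples) yields p = 1, OR = 1.

    Conditional on the margins, every table probability is the integer
    C(r,x)*C(n-r,k-x) over the common denominator C(n,k), so the tie rule
    "probability <= observed" is decided in exact integer arithmetic — no
    floating-point tie tolerance is involved.
    """
    if table.degenerate:
        return 1.0, 1.0
    a = table.both
    n = table.n
    r = table.both + table.a_only
    k = table.both + table.b_only
    num_obs = math.comb(r, a) * math.comb(n - r, k - a)
    total = 0
    for x in range(max(0, r + k - n), min(r, k) + 1):
        num_x = math.comb(r, x) * math.comb(n - r, k - x)
        if num_x <= num_obs:
            total += num_x
    p = total / math.comb(n, k)
    return min(p, 1.0), corrected_odds_ratio(table)


def _glm_from_table(table: ContingencyTable) -> tuple[float, float]:
    a, b, c, d = table.both, table.a_only, table.b_only, table.neither
    if table.degenerate:
        return 0.0, 1.0
    if min(a, b, c, d) == 0:
        # zero cell / complete separation: the unpenalized MLE diverges, so
        # cap the slope at +/-CAP and fall back to the Fisher p as the flag
        or_corr = corrected_odds_ratio(table)
        fisher_p, _ = fisher_exact(table)
        return math.copysign(GLM_COEF_CAP, math.log(or_corr)), fisher_p
    coef = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * float(stats.norm.sf(abs(coef) / se))
    return coef, min(p, 1.0)


def glm_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Logistic regression of binary y on binary x: slope and Wald p.

    For a single binary predictor the maximum-likelihood slope has the
    closed form log((both*neither)/(a_only*b_only)); the Wald standard error
    is sqrt of the summed reciprocal cell counts. Constant x or y is
    degenerate and returns (0, 1).
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, length >= 2")
    table = ContingencyTable(
        both=int((x & y).sum()),
        a_only=int((x & ~y).sum()),
        b_only=int((~x & y).sum()),
        neither=int((~x & ~y).sum()),
    )
    return _glm_from_table(table)


def _eligible_genes(matrix: MutationMatrix, min_mutated: int) -> list[str]:
    counts = matrix.values.sum(axis=1)
    return sorted(g for g, c in zip(matrix.genes, counts) if c >= min_mutated)


def pairwise_associations(
    matrix: MutationMatrix,
    min_mutated: int = 3,
    p_threshold: float = 0.001,
) -> list[AssociationRecord]:
    """Test every unordered pair of eligible genes for mutual exclusivity.

    A gene is eligible when mutated in at least ``min_mutated`` samples.
    Output is deterministic, one record per pair, sorted by (gene_a, gene_b)
    with genes in lexicographic order within a record.
    """
    genes = _eligible_genes(matrix, min_mutated)
    if len(genes) < 2:
        log.warning(
            "fewer than 2 genes mutated in >= %d samples; no pairs to test",
            min_mutated,
        )
        return []
    sub = np.stack([matrix.row(g) for g in genes]).astype(np.int64)
    n = matrix.n_samples
    row_sums = sub.sum(axis=1)
    both_counts = sub @ sub.T

    records: list[AssociationRecord] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            both = int(both_counts[i, j])
            a_only = int(row_sums[i]) - both
            b_only = int(row_sums[j]) - both
            table = ContingencyTable(both, a_only, b_only, n - both - a_only - b_only)
            fisher_p, or_corr = fisher_exact(table)
            glm_coef, glm_p = _glm_from_table(table)
            records.append(
                AssociationRecord(
                    gene_a=genes[i],
                    gene_b=genes[j],
                    table=table,
                    fisher_p=fisher_p,
                    odds_ratio=or_corr,
                    glm_coef=glm_coef,
                    glm_p=glm_p,
                    mutually_exclusive=bool(
                        or_corr < 1.0 and glm_coef < 0.0 and fisher_p < p_threshold
                    ),
                )
            )
    return records
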