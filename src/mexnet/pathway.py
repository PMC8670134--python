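"""Pathway overlay: extract connected subnetworks from modules (step 3).

Each module is intersected with a canonical pathway; connected components
of the induced pathway subgraph with at least three genes become
subnetworks, keeping the signal localized within the pathway. A combined
p-value per subnetwork aggregates the Fisher p-values of its mutually
exclusive gene pairs via Fisher's method. Because those pair tests share
samples they are not independent, so the combined value is a descriptive
score rather than a calibrated tail probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .association import AssociationRecord
from .cluster import ModulePartition
from .types import PathwayGraph

log = logging.getLogger(__name__)

__all__ = ["Subnetwork", "map_module", "combine_pvalues", "annotate_subnetworks"]


@dataclass
class Subnetwork:
    """A connected, pathway-restricted gene set from one module."""

    module_id: int
    pathway_name: str
    genes: set[str]
    pathway_edges: set[frozenset[str]]
    pair_pvalues: list[float]
    combined_p: float
    label: str


def map_module(
    module: set[str], pathway: PathwayGraph, min_size: int = 3
) -> list[set[str]]:
    """Connected components of the pathway subgraph induced by a module.

    Returns components of size >= ``min_size`` sorted by decreasing size
    (ties by smallest member gene); smaller components are discarded so a
    subnetwork stays localized rather than spreading across the pathway.
    """
    common = set(module) & pathway.nodes
    sub = pathway.graph.subgraph(common)
    components = [set(c) for c in nx.connected_components(sub) if len(c) >= min_size]
    components.sort(key=lambda c: (-len(c), min(c)))
    return components


def combine_pvalues(pvals) -> float:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square with 2k df.

    A p of exactly 0 is clamped to the smallest positive float with a
    warning. For k = 1 the combination is the identity.
    """
    pvals = list(pvals)
    if not pvals:
        raise ValueError("combine_pvalues requires at least one p-value")
    clean = []
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            log.warning("p-value of 0 clamped to smallest positive float")
            p = np.finfo(float).tiny
        clean.append(p)
    x = -2.0 * float(np.sum(np.log(clean)))
    return float(stats.chi2.sf(x, df=2 * len(clean)))


def annotate_subnetworks(
    modules: ModulePartition,
    pathway: PathwayGraph,
    records: list[AssociationRecord],
    min_size: int = 3,
    edge_cutoff: float | None = None,
) -> list[Subnetwork]:
    """Map every module onto the pathway and score the subnetworks.

    For each subnetwork gene set, the combined p-value aggregates the
    Fisher p of every within-set gene pair that is a mutual-exclusivity
    edge (optionally restricted to p < ``edge_cutoff``). Subnetworks with
    no qualifying pair are dropped with a warning. The display label joins
    the two members with the highest degree in the pathway graph.
    """
    mutex_p: dict[frozenset[str], float] = {}
    for rec in records:
        if rec.mutually_exclusive and (
            edge_cutoff is None or rec.fisher_p < edge_cutoff
        ):
            mutex_p[frozenset((rec.gene_a, rec.gene_b))] = rec.fisher_p

    subnetworks: list[Subnetwork] = []
    for module_id, module in enumerate(modules.modules):
        for genes in map_module(module, pathway, min_size=min_size):
            pairs = [
                frozenset((a, b))
                for i, a in enumerate(sorted(genes))
                for b in sorted(genes)[i + 1 :]
            ]
            pvals = [mutex_p[p] for p in pairs if p in mutex_p]
            if not pvals:
                log.warning(
                    "subnetwork %s in module %d has no mutually exclusive "
                    "pairs; dropped",
                    "-".join(sorted(genes)[:2]),
                    module_id,
                )
                continue
            # name by the two best-connected members in the pathway
            ranked = sorted(genes, key=lambda g: (-pathway.degree(g), g))
            label = f"{ranked[0]}-{ranked[1]}"
            edges = {
                frozenset((a, b))
                for a, b in pathway.graph.subgraph(genes).edges
            }
            subnetworks.append(
                Subnetwork(
                    module_id=module_id,
                    pathway_name=pathway.name,
                    genes=set(genes),
                    pathway_edges=edges,
                    pair_pvalues=sorted(pvals),
                    combined_p=combine_pvalues(pvals),
                    label=label,
                )
            )
    return subnetworks
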