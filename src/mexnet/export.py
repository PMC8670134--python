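"""Stage-artifact TSVs: writers and readers for pipeline intermediates.

Every output file starts with '#' comment lines recording tool version,
seed and thresholds, so each stage is independently inspectable and a rerun
with identical inputs reproduces byte-identical files.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from . import __version__
from .association import AssociationRecord, ContingencyTable
from .cluster import ModulePartition, MutexGraph
from .pathway import Subnetwork
from .survival import SurvivalResult
from .types import FormatError

__all__ = [
    "header_lines",
    "write_associations",
    "read_associations",
    "write_modules",
    "read_modules",
    "write_module_summary",
    "write_subnetworks",
    "read_subnetworks",
    "write_survival",
    "mutex_graphml",
    "subnetwork_overlay_graphml",
]


def header_lines(**params) -> list[str]:
    lines = [f"# mexnet {__version__}"]
    for key, value in params.items():
        lines.append(f"# {key}={value}")
    return lines


def _write_tsv(df: pd.DataFrame, path, params: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines(**params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


_ASSOC_COLUMNS = [
    "gene_a", "gene_b", "both", "a_only", "b_only", "neither",
    "fisher_p", "odds_ratio", "glm_coef", "glm_p", "mutually_exclusive",
]


def write_associations(records: list[AssociationRecord], path, **params) -> None:
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "both": r.table.both,
            "a_only": r.table.a_only,
            "b_only": r.table.b_only,
            "neither": r.table.neither,
            "fisher_p": f"{r.fisher_p:.5e}",
            "odds_ratio": f"{r.odds_ratio:.12g}",
            "glm_coef": f"{r.glm_coef:.12g}",
            "glm_p": f"{r.glm_p:.5e}",
            "mutually_exclusive": int(r.mutually_exclusive),
        }
        for r in records
    ]
    _write_tsv(pd.DataFrame(rows, columns=_ASSOC_COLUMNS), path, params)


def read_associations(path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"association TSV missing column(s): {', '.join(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AssociationRecord(
                gene_a=str(row.gene_a),
                gene_b=str(row.gene_b),
                table=ContingencyTable(
                    int(row.both), int(row.a_only), int(row.b_only), int(row.neither)
                ),
                fisher_p=float(row.fisher_p),
                odds_ratio=float(row.odds_ratio),
                glm_coef=float(row.glm_coef),
                glm_p=float(row.glm_p),
                mutually_exclusive=bool(int(row.mutually_exclusive)),
            )
        )
    return records


def write_modules(
    partition: ModulePartition, mutex: MutexGraph | None, path, **params
) -> None:
    """Per-gene module table with each gene's degree inside its module."""
    rows = []
    for module_id, module in enumerate(partition.modules):
        for gene in sorted(module):
            if mutex is not None and gene in mutex.graph:
                degree = sum(1 for nb in mutex.graph[gene] if nb in module)
            else:
                degree = 0
            rows.append(
                {"module_id": module_id, "gene": gene, "degree_in_module": degree}
            )
    params = {
        "edge_cutoff": partition.edge_cutoff,
        "clustering_seed": partition.seed,
        "modularity": f"{partition.modularity:.12g}",
        **params,
    }
    df = pd.DataFrame(rows, columns=["module_id", "gene", "degree_in_module"])
    _write_tsv(df, path, params)


def read_modules(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("module_id", "gene"):
        if col not in df.columns:
            raise FormatError(f"module TSV missing column: {col}")
    modules: dict[int, set[str]] = {}
    for row in df.itertuples(index=False):
        modules.setdefault(int(row.module_id), set()).add(str(row.gene))
    ordered = [modules[k] for k in sorted(modules)]
    return ModulePartition(
        modules=ordered,
        modularity=float("nan"),
        edge_cutoff=float("nan"),
        seed=-1,
        filtered=True,
    )


def write_module_summary(partition: ModulePartition, path, **params) -> None:
    df = pd.DataFrame(
        {"module_id": range(len(partition.modules)), "size": partition.sizes}
    )
    _write_tsv(df, path, params)


_SUBNET_COLUMNS = [
    "module_id", "pathway", "label", "n_genes", "genes", "n_pairs", "combined_p",
]


def write_subnetworks(subnetworks: list[Subnetwork], path, **params) -> None:
    rows = [
        {
            "module_id": s.module_id,
            "pathway": s.pathway_name,
            "label": s.label,
            "n_genes": len(s.genes),
            "genes": ",".join(sorted(s.genes)),
            "n_pairs": len(s.pair_pvalues),
            "combined_p": f"{s.combined_p:.5e}",
        }
        for s in subnetworks
    ]
    _write_tsv(pd.DataFrame(rows, columns=_SUBNET_COLUMNS), path, params)


def read_subnetworks(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _SUBNET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subnetwork TSV missing column(s): {', '.join(missing)}")
    return [
        {
            "module_id": int(row.module_id),
            "pathway": str(row.pathway),
            "label": str(row.label),
            "genes": set(str(row.genes).split(",")),
            "combined_p": float(row.combined_p),
        }
        for row in df.itertuples(index=False)
    ]


def write_survival(results: list[SurvivalResult], path, **params) -> None:
    rows = [
        {
            "basis": r.basis,
            "n_mutated": r.n_mutated,
            "n_non_mutated": r.n_non_mutated,
            "logrank_chisq": f"{r.logrank_chisq:.12g}",
            "logrank_p": f"{r.logrank_p:.5e}",
            "hr": f"{r.hr:.12g}",
            "coxph_p": f"{r.coxph_p:.5e}",
            "fdr": f"{r.fdr:.5e}",
        }
        for r in results
    ]
    columns = [
        "basis", "n_mutated", "n_non_mutated", "logrank_chisq", "logrank_p",
        "hr", "coxph_p", "fdr",
    ]
    _write_tsv(pd.DataFrame(rows, columns=columns), path, params)


def mutex_graphml(mutex: MutexGraph, partition: ModulePartition | None) -> nx.Graph:
    """Mutual-exclusivity graph with module labels, ready for GraphML export."""
    g = mutex.graph.copy()
    if partition is not None:
        member = partition.membership()
        for node in g.nodes:
            g.nodes[node]["module"] = int(member.get(node, -1))
    return g


def subnetwork_overlay_graphml(subnetworks: list[Subnetwork]) -> nx.Graph:
    """Pathway-edge overlay of all subnetworks, tagged per subnetwork label."""
    g = nx.Graph()
    for s in subnetworks:
        for gene in sorted(s.genes):
            g.add_node(gene, subnetwork=s.label, module=int(s.module_id))
        for edge in sorted(tuple(sorted(e)) for e in s.pathway_edges):
            g.add_edge(*edge, subnetwork=s.label)
    return g
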