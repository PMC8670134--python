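"""Readers and writers for every external format the pipeline touches.

Formats: MAF (GDC dialect, tab-separated), binary mutation-matrix TSV,
two-column pathway edge lists, clinical TSV, and GraphML exports. All text
output is UTF-8 and tab-separated unless GraphML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ClinicalTable,
    EmptyMatrixError,
    FormatError,
    MutationMatrix,
    PathwayGraph,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_VARIANT_CLASSES",
    "read_maf",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_pathway_edgelist",
    "write_pathway_edgelist",
    "read_clinical",
    "write_clinical",
    "write_graphml",
    "read_graphml",
]

# Qualifying single-nucleotide variant classes. GDC MAF spells the stop-gain
# class "Nonsense_Mutation"; the synonym set accepts both spellings,
# case-insensitively.
DEFAULT_VARIANT_CLASSES = frozenset(
    {
        "missense_mutation",
        "missense",
        "start_lost",
        "nonsense_mutation",
        "stop_gained",
        "stop_lost",
    }
)

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(path, included_classes=None) -> MutationMatrix:
    """Binarize a MAF file into a gene x sample mutation matrix.

    Entry (g, s) is 1 iff at least one record for gene g in sample s has a
    Variant_Classification in ``included_classes`` (matched
    case-insensitively). The sample universe is every distinct
    Tumor_Sample_Barcode in the file, including samples whose only records
    were filtered out, so downstream mutation frequencies are per-cohort.
    Genes with zero qualifying records are absent from the matrix.
    """
    if included_classes is None:
        classes = set(DEFAULT_VARIANT_CLASSES)
    else:
        classes = {c.lower() for c in included_classes}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file missing required column(s): {', '.join(missing)}")

    samples = sorted(df["Tumor_Sample_Barcode"].dropna().unique())
    keep = df["Variant_Classification"].str.lower().isin(classes)
    kept = df.loc[keep, ["Hugo_Symbol", "Tumor_Sample_Barcode"]].dropna()
    if kept.empty:
        raise EmptyMatrixError(
            "no MAF records remain after variant-class filtering"
        )
    genes = sorted(kept["Hugo_Symbol"].unique())
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for g, s in kept.itertuples(index=False):
        values[gidx[g], sidx[s]] = 1

    n_untouched = int((values.sum(axis=0) == 0).sum())
    if n_untouched:
        log.info(
            "%d of %d samples carry no qualifying mutation but are retained "
            "in the cohort denominator",
            n_untouched,
            len(samples),
        )
    return MutationMatrix(genes=genes, samples=samples, values=values)


def write_mutation_matrix(matrix: MutationMatrix, path, header_lines=()) -> None:
    """Write a mutation matrix as TSV: first column gene symbol, then samples."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for g, row in zip(matrix.genes, matrix.values):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_mutation_matrix(path) -> MutationMatrix:
    """Read a gene x sample 0/1 matrix TSV (round-trips with the writer)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("mutation matrix TSV needs a gene column plus samples")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    dup = pd.Series(genes)[pd.Series(genes).duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated gene row: {dup.iloc[0]!r}")
    samples = list(df.columns[1:])
    body = df[samples]
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for i, gene in enumerate(genes):
        for j, sample in enumerate(samples):
            cell = body.iat[i, j]
            if cell not in ("0", "1"):
                raise FormatError(
                    f"non-binary entry {cell!r} at gene row {i + 1} "
                    f"({gene!r}), column {sample!r}"
                )
            values[i, j] = int(cell)
    return MutationMatrix(genes=genes, samples=samples, values=values)


def read_pathway_edgelist(path, name: str) -> PathwayGraph:
    """Read a two-column gene-pair TSV into an undirected pathway graph.

    Reversed duplicates collapse to a single edge; self-loops are dropped
    with a logged warning. Lines starting with '#' are comments.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"pathway edge list line {lineno}: expected two "
                    f"tab-separated columns, got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                log.warning("dropping self-loop %s-%s in pathway %s", a, b, name)
                continue
            g.add_edge(a, b)
    return PathwayGraph(name=name, graph=g)


def write_pathway_edgelist(pathway: PathwayGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pathway: {pathway.name}\n")
        for a, b in sorted(tuple(sorted(e)) for e in pathway.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_clinical(path) -> ClinicalTable:
    """Read the clinical TSV (columns: sample, time, event, age, sex)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    """Export a graph to GraphML, preserving node/edge attributes."""
    path = Path(path)
    try:
        nx.write_graphml(graph, path)
    except OSError as exc:
        raise OSError(f"cannot write GraphML to {path}: {exc}") from exc


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
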