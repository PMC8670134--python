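"""Core in-memory containers shared across the pipeline stages.

The pipeline operates on a binary gene x sample incidence matrix of
qualifying somatic mutations, an undirected canonical-pathway graph, and a
per-sample clinical table (follow-up time, event indicator, age, sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MutationMatrix",
    "PathwayGraph",
    "ClinicalTable",
    "FormatError",
    "EmptyMatrixError",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class EmptyMatrixError(FormatError):
    """Raised when parsing yields a mutation matrix with no genes."""


@dataclass
class MutationMatrix:
    """Binary gene x sample incidence of qualifying somatic mutations.

    ``values[i, j] == 1`` iff gene ``genes[i]`` carries at least one
    qualifying mutation in sample ``samples[j]``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols in mutation matrix")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample identifiers in mutation matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary entry at gene {self.genes[i]!r}, "
                f"sample {self.samples[j]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene: str) -> np.ndarray:
        """Return the 0/1 incidence vector for one gene."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in mutation matrix") from None

    def gene_frequencies(self) -> pd.Series:
        """Per-gene mutated-sample counts."""
        return pd.Series(self.values.sum(axis=1), index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PathwayGraph:
    """Undirected canonical-pathway topology over gene symbols."""

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]


SEX_LEVELS = ("male", "female", "unknown")


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus age and sex covariates.

    ``time`` is the follow-up duration in a caller-declared unit (uniform per
    table); ``event`` is 1 for an observed death and 0 for censoring.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "time", "event", "age", "sex"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing column(s): {', '.join(missing)}")
        df = self.data[required].copy()
        df["sample"] = df["sample"].astype(str)
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise FormatError(f"duplicate clinical row for sample {dup!r}")
        df["time"] = pd.to_numeric(df["time"])
        if (df["time"] <= 0).any():
            raise FormatError("clinical time values must be > 0")
        df["event"] = pd.to_numeric(df["event"]).astype(int)
        if not df["event"].isin([0, 1]).all():
            raise FormatError("clinical event values must be 0 or 1")
        df["age"] = pd.to_numeric(df["age"])
        df["sex"] = df["sex"].astype(str).str.lower()
        if not df["sex"].isin(SEX_LEVELS).all():
            bad = df.loc[~df["sex"].isin(SEX_LEVELS), "sex"].iloc[0]
            raise FormatError(f"unrecognized sex value {bad!r}")
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()
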