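"""End-to-end orchestration: associate -> cluster -> map -> survive.

Each stage writes its TSV artifact; a run manifest records the tool
version, seed, thresholds, and input checksums. Reruns with the same
configuration and inputs reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, export, io
from .association import pairwise_associations
from .cluster import (
    DEFAULT_CUTOFF_GRID,
    build_graph,
    filter_modules,
    louvain_cluster,
    tune_cutoff,
)
from .pathway import annotate_subnetworks
from .survival import analyze_bases

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and reproducibility knobs for one pipeline run."""

    maf: str | None = None
    matrix: str | None = None
    pathway: str | None = None
    clinical: str | None = None
    out_dir: str = "mexnet-out"
    p_threshold: float = 0.001
    edge_cutoff: float = 1e-8
    min_module_size: int = 3
    min_subnetwork_size: int = 3
    min_mutated: int = 3
    tune: bool = False
    target_min: int = 5
    target_max: int = 10
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.maf and not self.matrix:
            raise ValueError("config needs a maf or matrix input")
        for name in ("p_threshold", "edge_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("min_module_size", "min_subnetwork_size", "min_mutated"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoff_grid" in raw:
            raw["cutoff_grid"] = tuple(float(c) for c in raw["cutoff_grid"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "edge_cutoff": config.edge_cutoff,
            "min_module_size": config.min_module_size,
            "min_subnetwork_size": config.min_subnetwork_size,
            "min_mutated": config.min_mutated,
        },
        "inputs": {},
        "tables": {},
    }
    for name in ("maf", "matrix", "pathway", "clinical"):
        path = getattr(config, name)
        if path:
            try:
                manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
            except OSError as exc:
                raise StageError(_input_stage(name), f"cannot read {path}: {exc}")

    # -- associate ---------------------------------------------------------
    try:
        if config.matrix:
            matrix = io.read_mutation_matrix(config.matrix)
        else:
            matrix = io.read_maf(config.maf)
        records = pairwise_associations(
            matrix, min_mutated=config.min_mutated, p_threshold=config.p_threshold
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("associate", str(exc)) from exc
    assoc_path = out / "associations.tsv"
    _atomic(
        assoc_path,
        lambda p: export.write_associations(
            records,
            p,
            seed=config.seed,
            p_threshold=config.p_threshold,
            min_mutated=config.min_mutated,
        ),
    )
    manifest["tables"]["associations"] = assoc_path.name
    # downstream stages consume the written table, not the in-memory records,
    # so a staged rerun from the TSV reproduces the pipeline bit-exactly
    records = export.read_associations(assoc_path)
    n_mutex = sum(r.mutually_exclusive for r in records)
    log.info(
        "associate: %d genes tested, %d pairs, %d mutually exclusive",
        matrix.n_genes, len(records), n_mutex,
    )

    # -- cluster -----------------------------------------------------------
    try:
        if config.tune:
            cutoff, partition = tune_cutoff(
                records,
                target_range=(config.target_min, config.target_max),
                grid=config.cutoff_grid,
                seed=config.seed,
                min_module_size=config.min_module_size,
            )
        else:
            cutoff = config.edge_cutoff
            partition = filter_modules(
                louvain_cluster(build_graph(records, cutoff), seed=config.seed),
                min_size=config.min_module_size,
            )
        mutex = build_graph(records, cutoff)
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc
    manifest["thresholds"]["edge_cutoff"] = cutoff
    modules_path = out / "modules.tsv"
    _atomic(
        modules_path,
        lambda p: export.write_modules(
            partition, mutex, p, seed=config.seed, tuned=int(config.tune)
        ),
    )
    _atomic(
        out / "module_summary.tsv",
        lambda p: export.write_module_summary(
            partition, p, edge_cutoff=cutoff, seed=config.seed
        ),
    )
    io.write_graphml(export.mutex_graphml(mutex, partition), out / "mutex_graph.graphml")
    manifest["tables"]["modules"] = modules_path.name
    log.info(
        "cluster: cutoff %.3g, %d edges kept, %d modules of size >= %d",
        cutoff, mutex.n_edges, len(partition.modules), config.min_module_size,
    )

    # -- map ---------------------------------------------------------------
    subnetworks = []
    if config.pathway:
        try:
            pathway = io.read_pathway_edgelist(
                config.pathway, name=Path(config.pathway).stem
            )
            subnetworks = annotate_subnetworks(
                partition,
                pathway,
                records,
                min_size=config.min_subnetwork_size,
                edge_cutoff=None,
            )
        except Exception as exc:
            raise StageError("map", str(exc)) from exc
        sub_path = out / "subnetworks.tsv"
        _atomic(
            sub_path,
            lambda p: export.write_subnetworks(
                subnetworks,
                p,
                seed=config.seed,
                min_subnetwork_size=config.min_subnetwork_size,
            ),
        )
        io.write_graphml(
            export.subnetwork_overlay_graphml(subnetworks),
            out / "subnetwork_overlay.graphml",
        )
        manifest["tables"]["subnetworks"] = sub_path.name
        log.info("map: %d subnetworks kept", len(subnetworks))

    # -- survive -----------------------------------------------------------
    if config.clinical:
        try:
            clinical = io.read_clinical(config.clinical)
            bases: dict[str, set[str]] = {}
            for s in subnetworks:
                bases[s.label] = set(s.genes)
                for gene in sorted(s.genes):
                    bases.setdefault(gene, {gene})
            if not bases:
                log.warning("survive: no subnetworks to test; stage skipped")
            else:
                results = analyze_bases(matrix, clinical, bases)
                surv_path = out / "survival.tsv"
                _atomic(
                    surv_path,
                    lambda p: export.write_survival(results, p, seed=config.seed),
                )
                manifest["tables"]["survival"] = surv_path.name
                log.info("survive: %d bases tested", len(results))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("survive", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _input_stage(name: str) -> str:
    return {
        "maf": "associate",
        "matrix": "associate",
        "pathway": "map",
        "clinical": "survive",
    }[name]


def _atomic(path: Path, writer) -> None:
    """Write via a .partial file so failures never leave a truncated table."""
    partial = path.with_suffix(path.suffix + ".partial")
    try:
        writer(partial)
    except Exception:
        raise
    partial.replace(path)


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)
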