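"""Survival comparison of mutated vs. non-mutated sample groups.

Samples are grouped by mutation status over a gene set (a single gene or
all genes of a subnetwork); the two groups are compared with the log-rank
test and a Cox proportional-hazards model adjusted for sex and age (Efron
tie handling). Benjamini-Hochberg FDR is applied across the batch of
bases tested in one run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests

from .types import ClinicalTable, MutationMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalResult",
    "group_by_genes",
    "logrank_test",
    "coxph_adjusted",
    "bh_fdr",
    "life_table",
    "analyze_bases",
]

MUTATED = "mutated"
NON_MUTATED = "non_mutated"


@dataclass
class SurvivalResult:
    """Two-group survival comparison for one basis (gene or subnetwork)."""

    basis: str
    n_mutated: int
    n_non_mutated: int
    logrank_chisq: float
    logrank_p: float
    hr: float
    coxph_p: float
    fdr: float = float("nan")


def group_by_genes(
    matrix: MutationMatrix, genes, clinical: ClinicalTable
) -> pd.DataFrame:
    """Assign each clinical sample to mutated / non-mutated by a gene set.

    A sample is ``mutated`` iff it carries at least one mutation in any
    listed gene. Clinical samples absent from the matrix are dropped with a
    warning; an empty intersection is an error.
    """
    genes = sorted(set(genes))
    rows = np.stack([matrix.row(g) for g in genes])
    mutated_samples = {
        s for s, hit in zip(matrix.samples, rows.any(axis=0)) if hit
    }
    known = set(matrix.samples)
    clin_samples = clinical.samples
    dropped = [s for s in clin_samples if s not in known]
    if len(dropped) == len(clin_samples):
        raise ValueError("no clinical sample is present in the mutation matrix")
    if dropped:
        log.warning(
            "%d clinical samples absent from the mutation matrix were dropped",
            len(dropped),
        )
    kept = [s for s in clin_samples if s in known]
    return pd.DataFrame(
        {
            "sample": kept,
            "group": [MUTATED if s in mutated_samples else NON_MUTATED for s in kept],
        }
    )


def _merged(groups: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    df = groups.merge(clinical.data, on="sample", how="inner")
    df["mutated"] = (df["group"] == MUTATED).astype(int)
    return df


def logrank_test(groups: pd.DataFrame, clinical: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank statistic and chi-square(1) p-value."""
    df = _merged(groups, clinical)
    a = df[df["mutated"] == 1]
    b = df[df["mutated"] == 0]
    if a.empty or b.empty:
        raise ValueError("log-rank test requires two non-empty groups")
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        log.warning("no events in either group; log-rank test degenerate")
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def coxph_adjusted(
    groups: pd.DataFrame, clinical: ClinicalTable
) -> tuple[float, float]:
    """Cox PH fit of group + age + sex; returns (hazard ratio, Wald p).

    Sex is coded as a 0/1 indicator (male = 1); samples with unknown sex
    are dropped. When a covariate is constant in the cohort it is removed
    from the model with a log message. Non-convergence is flagged with
    hr = nan, p = 1.
    """
    df = _merged(groups, clinical)
    n_unknown = int((df["sex"] == "unknown").sum())
    if n_unknown:
        log.warning("dropping %d samples with unknown sex", n_unknown)
        df = df[df["sex"] != "unknown"]
    df = df.assign(sex01=(df["sex"] == "male").astype(int))
    covariates = ["mutated"]
    for cov in ("age", "sex01"):
        if df[cov].nunique() > 1:
            covariates.append(cov)
        else:
            log.info("covariate %s is constant; dropped from the Cox model", cov)
    fit_df = df[["time", "event", *covariates]]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        log.warning("Cox model did not converge: %s", exc)
        return float("nan"), 1.0
    hr = float(np.exp(cph.params_["mutated"]))
    p = float(cph.summary.loc["mutated", "p"])
    return hr, min(p, 1.0)


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    pvals = list(pvals)
    if not pvals:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])


def life_table(groups: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    """Per-event-time at-risk and event counts for each group.

    Enough to draw Kaplan-Meier curves with any external plotter.
    """
    df = _merged(groups, clinical)
    times = sorted(df.loc[df["event"] == 1, "time"].unique())
    rows = []
    for t in times:
        m = df[df["mutated"] == 1]
        nm = df[df["mutated"] == 0]
        rows.append(
            {
                "time": t,
                "at_risk_mutated": int((m["time"] >= t).sum()),
                "events_mutated": int(((m["time"] == t) & (m["event"] == 1)).sum()),
                "at_risk_non": int((nm["time"] >= t).sum()),
                "events_non": int(((nm["time"] == t) & (nm["event"] == 1)).sum()),
            }
        )
    return pd.DataFrame(rows, columns=[
        "time", "at_risk_mutated", "events_mutated", "at_risk_non", "events_non",
    ])


def analyze_bases(
    matrix: MutationMatrix,
    clinical: ClinicalTable,
    bases: dict[str, set[str]],
) -> list[SurvivalResult]:
    """Run the two-group comparison for every basis and apply BH FDR.

    ``bases`` maps a label (gene symbol or subnetwork label) to the gene
    set defining the mutated group; single genes and subnetwork groups are
    adjusted together as one batch.
    """
    results: list[SurvivalResult] = []
    for label, genes in bases.items():
        groups = group_by_genes(matrix, genes, clinical)
        n_mut = int((groups["group"] == MUTATED).sum())
        n_non = int((groups["group"] == NON_MUTATED).sum())
        if n_mut == 0 or n_non == 0:
            log.warning("basis %s has a one-sided grouping; skipped", label)
            continue
        chisq, lr_p = logrank_test(groups, clinical)
        hr, cox_p = coxph_adjusted(groups, clinical)
        results.append(
            SurvivalResult(label, n_mut, n_non, chisq, lr_p, hr, cox_p)
        )
    adjusted = bh_fdr([r.coxph_p for r in results])
    for r, fdr in zip(results, adjusted):
        r.fdr = float(fdr)
    return results
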