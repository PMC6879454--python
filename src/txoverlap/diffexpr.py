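"""Differential expression calling and signature construction.

Dysregulated transcripts are called per dataset with Welch's unequal-variance
t-test (two-sided, Welch-Satterthwaite degrees of freedom), Benjamini-Hochberg
FDR across all probes of the dataset, and a fold change computed against the
median of the control samples on the log2 scale. Signatures collapse probes to
genes by the minimum-p representative and can be truncated to equal sizes so
that lists from studies of very different power are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ConfigError,
    DiseaseSignature,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
)

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "probe_id",
    "gene",
    "mean_case",
    "mean_control",
    "log2fc",
    "fold_change",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "direction",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for calling a probe dysregulated.

    ``use_fdr`` applies the cutoff to BH-adjusted q-values (the convention for
    well-powered human disease datasets); off, the raw p-value is thresholded.
    ``fc_cutoff`` is a linear fold-change ratio >= 1; probes pass when the
    control-median fold change is >= fc_cutoff or <= 1/fc_cutoff.
    """

    p_cutoff: float = 0.05
    use_fdr: bool = True
    fc_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff <= 1):
            raise ConfigError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if self.fc_cutoff < 1:
            raise ConfigError(f"fc_cutoff must be >= 1, got {self.fc_cutoff}")


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, Satterthwaite df, two-sided p).

    Both groups need >= 2 observations. The degenerate limit of zero variance
    in both groups with equal means is defined as t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigError("welch_t_test needs >= 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigError("welch_t_test requires finite values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_vs_control_median(case_values, control_values) -> tuple[float, float]:
    """Fold change normalized to the median of the control samples.

    Inputs are log2-scale; returns (log2fc, linear fold change 2**log2fc).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ConfigError("fold change needs >= 1 value per group")
    log2fc = float(np.median(case) - np.median(control))
    return log2fc, float(2.0**log2fc)


def differential_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    annotation: ProbeAnnotation | None = None,
) -> pd.DataFrame:
    """Per-probe Welch test, BH q over all probes, and control-median fold change.

    Returns one row per probe, ordered by probe id; q-values are computed over
    all probes of this dataset (FDR is per dataset, never pooled).
    """
    design.check_against(matrix)
    case_ids = design.case_samples
    ctrl_ids = design.control_samples
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ConfigError("differential expression needs >= 2 samples per group")
    X = matrix.values[case_ids].to_numpy()
    Y = matrix.values[ctrl_ids].to_numpy()

    res = stats.ttest_ind(X, Y, axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float, copy=True)
    p = np.array(res.pvalue, dtype=float, copy=True)
    df = np.array(res.df, dtype=float, copy=True)

    # zero variance in both groups: scipy yields nan; use the defined limits
    both_const = (X.var(axis=1, ddof=1) == 0) & (Y.var(axis=1, ddof=1) == 0)
    if both_const.any():
        mean_diff = X.mean(axis=1) - Y.mean(axis=1)
        eq = both_const & (mean_diff == 0)
        ne = both_const & (mean_diff != 0)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.where(mean_diff[ne] > 0, np.inf, -np.inf)
        p[ne] = 0.0
        df[both_const] = X.shape[1] + Y.shape[1] - 2

    log2fc = np.median(X, axis=1) - np.median(Y, axis=1)
    q = bh_adjust(p)

    genes = (
        [annotation.gene_of(pid) for pid in matrix.probe_ids]
        if annotation is not None
        else [""] * matrix.n_probes
    )
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "gene": genes,
            "mean_case": X.mean(axis=1),
            "mean_control": Y.mean(axis=1),
            "log2fc": log2fc,
            "fold_change": 2.0**log2fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    )
    return out.sort_values("probe_id", kind="mergesort").reset_index(drop=True)


def select_signature(
    records: pd.DataFrame,
    annotation: ProbeAnnotation,
    config: SelectionConfig,
    label: str,
) -> DiseaseSignature:
    """Filter DE records and collapse probes to a gene-level signature.

    A probe passes when its (q if ``use_fdr`` else p) <= cutoff AND its linear
    fold change is >= fc_cutoff or <= 1/fc_cutoff. Unannotated probes are
    dropped (count logged); multiple probes of one gene collapse to the probe
    with the smallest p-value, ties broken by probe id.
    """
    stat = records["q_value"] if config.use_fdr else records["p_value"]
    fc = records["fold_change"]
    passing = records[
        (stat <= config.p_cutoff)
        & ((fc >= config.fc_cutoff) | (fc <= 1.0 / config.fc_cutoff))
    ].copy()

    passing["gene"] = [
        annotation.gene_of(pid) if not g else g
        for pid, g in zip(passing["probe_id"], passing["gene"])
    ]
    n_unannotated = int((passing["gene"] == "").sum())
    if n_unannotated:
        logger.info("%s: dropped %d unannotated passing probes", label, n_unannotated)
    passing = passing[passing["gene"] != ""]

    passing = passing.sort_values(["p_value", "probe_id"], kind="mergesort")
    best = passing.drop_duplicates(subset="gene", keep="first")

    directions = {g: (1 if d == "up" else -1) for g, d in zip(best["gene"], best["direction"])}
    pvalues = {g: float(p) for g, p in zip(best["gene"], best["p_value"])}
    if not directions:
        logger.warning("%s: empty signature (no probe passed selection)", label)
    return DiseaseSignature(
        label=label, taxon=annotation.taxon, directions=directions, pvalues=pvalues
    )


def equalize_signatures(
    signatures: list[DiseaseSignature], target_size: int | None = None
) -> list[DiseaseSignature]:
    """Truncate signatures to a common size, keeping the smallest-p genes.

    Default target is the size of the smallest input signature. Ties at the
    cut are broken by gene symbol lexicographic order. Inputs are untouched.
    """
    if len(signatures) < 2:
        raise ConfigError("equalize_signatures needs >= 2 signatures")
    if target_size is None:
        target_size = min(len(s) for s in signatures)
    too_small = [s.label for s in signatures if len(s) < target_size]
    if too_small:
        raise ConfigError(
            f"target_size {target_size} exceeds signature size for: {too_small}"
        )
    out = []
    for sig in signatures:
        ranked = sorted(sig.directions, key=lambda g: (sig.pvalues.get(g, np.inf), g))
        keep = ranked[:target_size]
        out.append(
            DiseaseSignature(
                label=sig.label,
                taxon=sig.taxon,
                directions={g: sig.directions[g] for g in keep},
                pvalues={g: sig.pvalues[g] for g in keep if g in sig.pvalues},
            )
        )
    return out
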