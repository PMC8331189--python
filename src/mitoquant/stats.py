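"""Study-level statistics.

Turns per-image quantitation records into the study's reported quantities:

- a mitophagic-cell count threshold set from the reference (untreated WT)
  condition via a trimmed mean, and the resulting percentage of mitophagic
  cells (outliers are excluded only when setting the threshold, never from
  the classified data);
- per-subject averaging (the subject is the unit of analysis);
- one-way / two-way ANOVA with Tukey HSD post-hoc comparisons and the
  usual significance stars;
- electron-microscopy score aggregation (percentage of structures
  containing mitochondria, fold-change with the control of each
  experiment normalized to 1);
- the two-sample, two-sided equality sample-size calculation used to power
  the animal cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if not np.isfinite(p):
        return ""
    for thr, code in STAR_THRESHOLDS:
        if p < thr:
            return code
    return "ns"


# ---------------------------------------------------------------------------
# trimmed means and the mitophagic-cell threshold
# ---------------------------------------------------------------------------


def truncated_mean(values: Sequence[float], trim_fraction: float = 0.2) -> float:
    """Symmetric trimmed mean.

    Drops ``floor(trim_fraction * n)`` smallest and largest values and
    averages the rest.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values is empty")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    k = int(np.floor(trim_fraction * x.size))
    kept = np.sort(x)[k: x.size - k] if k > 0 else x
    if kept.size == 0:
        raise ValueError("trimming removed every value")
    return float(kept.mean())


def iqr_fence_mean(values: Sequence[float], k: float = 1.5) -> float:
    """Mean after removing values outside Tukey IQR fences (alternative
    outlier rule to the fixed-fraction trim)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values is empty")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    kept = x[(x >= q1 - k * iqr) & (x <= q3 + k * iqr)]
    if kept.size == 0:
        raise ValueError("fences removed every value")
    return float(kept.mean())


@dataclass
class MitophagicThreshold:
    """Mitolysosomes-per-cell threshold derived from a reference condition."""

    value: float
    trim_fraction: float = 0.2
    source_condition: str = "WT/untreated"
    method: str = "truncated_mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")


def mitophagic_threshold(
    reference_counts: Sequence[float],
    trim_fraction: float = 0.2,
    source_condition: str = "WT/untreated",
    method: str = "truncated_mean",
) -> MitophagicThreshold:
    """Set the threshold from reference-condition per-cell counts.

    ``method`` is ``"truncated_mean"`` (fixed symmetric trim, default) or
    ``"iqr_fence"`` (mean after Tukey-fence outlier removal).
    """
    if method == "truncated_mean":
        value = truncated_mean(reference_counts, trim_fraction)
    elif method == "iqr_fence":
        value = iqr_fence_mean(reference_counts)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return MitophagicThreshold(
        value=value,
        trim_fraction=trim_fraction,
        source_condition=source_condition,
        method=method,
    )


def classify_mitophagic_cells(
    per_cell_counts: Sequence[float], threshold: MitophagicThreshold
) -> float:
    """Percentage of cells strictly above the threshold.

    All cells are classified — outlier removal only ever applied to the
    threshold-setting reference data, never here.
    """
    counts = np.asarray(per_cell_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("per_cell_counts is empty")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    return float(100.0 * np.mean(counts > threshold.value))


# ---------------------------------------------------------------------------
# subject-level aggregation
# ---------------------------------------------------------------------------


def summarize_by_subject(
    records: pd.DataFrame,
    outcome: str,
    group_cols: Sequence[str] = ("subject_id", "genotype", "treatment", "cell_type"),
) -> pd.DataFrame:
    """Unweighted mean of the image-level outcome per subject.

    Returns one row per subject (and grouping metadata) with columns
    ``mean_<outcome>`` and ``n_images``.
    """
    if "subject_id" not in group_cols:
        raise ValueError("group_cols must include subject_id")
    missing = [c for c in (*group_cols, outcome) if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns: {missing}")
    if records["subject_id"].isna().any() or (records["subject_id"] == "").any():
        raise ValueError("records with missing subject_id")
    grouped = records.groupby(list(group_cols), dropna=False)[outcome]
    out = grouped.agg(["mean", "size"]).reset_index()
    out = out.rename(columns={"mean": f"mean_{outcome}", "size": "n_images"})
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    table: pd.DataFrame  # term, sum_sq, df, F, p
    formula: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class TukeyResult:
    table: pd.DataFrame  # group1, group2, meandiff, p_adj, stars, reject


def anova_tukey(
    summaries: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
) -> tuple[AnovaResult, TukeyResult]:
    """ANOVA over subject means followed by Tukey HSD on all cell pairs.

    One factor gives a one-way ANOVA; two factors a two-way ANOVA with
    interaction and type-II sums of squares (the conventional choice for
    the mildly unbalanced designs seen here).  Tukey compares every
    factor-level combination.  Empty design cells are reported in
    ``AnovaResult.warnings``, never silently dropped.
    """
    factors = list(factors)
    if len(factors) not in (1, 2):
        raise ValueError("factors must name one or two columns")
    missing = [c for c in (*factors, outcome) if c not in summaries.columns]
    if missing:
        raise ValueError(f"summary table lacks columns: {missing}")
    df = summaries.copy()

    warnings: list[str] = []
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    levels = [sorted(df[f].astype(str).unique()) for f in factors]
    for combo in itertools.product(*levels):
        sel = np.ones(len(df), dtype=bool)
        for f, lv in zip(factors, combo):
            sel &= df[f].astype(str).values == lv
        n = int(sel.sum())
        if n == 0:
            warnings.append(f"empty design cell: {dict(zip(factors, combo))}")
        elif n < 2:
            warnings.append(f"design cell with a single subject: {dict(zip(factors, combo))}")

    terms = " * ".join(f"C({f})" for f in factors)
    formula = f"{outcome} ~ {terms}"
    model = ols(formula, data=df).fit()
    typ = 2 if len(factors) == 2 else 1
    raw = anova_lm(model, typ=typ)
    table = raw.reset_index().rename(columns={
        "index": "term", "PR(>F)": "p", "F": "F",
    })
    anova = AnovaResult(table=table, formula=formula, warnings=warnings)

    cell = df[factors[0]].astype(str)
    for f in factors[1:]:
        cell = cell + ":" + df[f].astype(str)
    hsd = pairwise_tukeyhsd(df[outcome].to_numpy(dtype=float), cell.to_numpy())
    frame = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    )
    tukey_table = pd.DataFrame({
        "group1": frame["group1"].astype(str),
        "group2": frame["group2"].astype(str),
        "meandiff": frame["meandiff"].astype(float),
        "p_adj": np.asarray(hsd.pvalues, dtype=float),
        "reject": np.asarray(hsd.reject, dtype=bool),
    })
    tukey_table["stars"] = [stars(p) for p in tukey_table["p_adj"]]
    return anova, TukeyResult(table=tukey_table)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------


@dataclass
class PowerParams:
    """Inputs to the two-sample, two-sided equality sample-size formula."""

    mu: float
    sd: float
    effect_fraction: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.effect_fraction <= 0:
            raise ValueError("effect_fraction must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


def sample_size_two_means(p: PowerParams) -> tuple[float, int]:
    """Per-group n for a two-sample, two-sided equality design.

    delta = effect_fraction * mu;
    n = 2 * sd^2 * (z_{1-alpha/2} + z_{power})^2 / delta^2.
    Returns (unrounded n, nearest integer floored at 1).
    """
    delta = p.effect_fraction * p.mu
    if delta == 0:
        raise ValueError("detectable difference is zero")
    z_alpha = sps.norm.ppf(1.0 - p.alpha / 2.0)
    z_power = sps.norm.ppf(p.power)
    n_unrounded = 2.0 * p.sd**2 * (z_alpha + z_power) ** 2 / delta**2
    n_per_group = max(int(round(n_unrounded)), 1)
    return float(n_unrounded), n_per_group


def analytic_power_two_means(p: PowerParams, n_per_group: int) -> float:
    """Normal-approximation power of the two-group design at a given n."""
    delta = p.effect_fraction * p.mu
    z_alpha = sps.norm.ppf(1.0 - p.alpha / 2.0)
    ncp = abs(delta) / (p.sd * np.sqrt(2.0 / n_per_group))
    return float(sps.norm.cdf(ncp - z_alpha) + sps.norm.cdf(-ncp - z_alpha))


# ---------------------------------------------------------------------------
# electron-microscopy score aggregation
# ---------------------------------------------------------------------------


def tem_scores(
    scores: pd.DataFrame,
    control_arm: str = "control",
    experiment_col: str = "experiment",
    arm_col: str = "arm",
    with_col: str = "n_with_mito",
    total_col: str = "n_total",
) -> pd.DataFrame:
    """Aggregate blinded per-image scores to per-arm percentages and folds.

    Counts are pooled per (experiment, arm):
    ``pct_with_mito = 100 * sum(with) / sum(total)``; the fold column
    normalizes each experiment's control arm to 1
    (``fold = pct_arm / pct_control``), flagged missing when the control
    percentage is 0.
    """
    for c in (experiment_col, arm_col, with_col, total_col):
        if c not in scores.columns:
            raise ValueError(f"scores table lacks column {c!r}")
    if np.any(scores[with_col].to_numpy() > scores[total_col].to_numpy()):
        raise ValueError("n_with_mito exceeds n_total in some rows")
    pooled = (
        scores.groupby([experiment_col, arm_col])[[with_col, total_col]]
        .sum()
        .reset_index()
    )
    pooled["pct_with_mito"] = np.where(
        pooled[total_col] > 0,
        100.0 * pooled[with_col] / pooled[total_col],
        np.nan,
    )
    folds = []
    for _, row in pooled.iterrows():
        ctrl = pooled[
            (pooled[experiment_col] == row[experiment_col])
            & (pooled[arm_col] == control_arm)
        ]
        if ctrl.empty:
            raise ValueError(
                f"experiment {row[experiment_col]!r} has no {control_arm!r} arm"
            )
        ctrl_pct = float(ctrl["pct_with_mito"].iloc[0])
        if not np.isfinite(ctrl_pct) or ctrl_pct == 0:
            folds.append(float("nan"))
        else:
            folds.append(float(row["pct_with_mito"]) / ctrl_pct)
    pooled["fold_vs_control"] = folds
    return pooled
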