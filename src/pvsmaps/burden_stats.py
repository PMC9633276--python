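"""PVS-burden metrics, progression classification, and association models.

Burden is summarized per scan as the accepted-cluster count and total
voxel volume, each also reported adjusted per 100 mL of white matter.
Longitudinal associations between burden and cognition or fluid
biomarkers are estimated with linear mixed models: fixed effects for the
predictor plus covariates (age, smoking history, mean arterial blood
pressure, time of day — standardized), and a per-subject random
intercept, fitted by REML. Within-subject week-52 minus baseline change
analyses use the same covariate-adjusted fixed-effects structure on the
deltas (one row per subject, ordinary least squares). No multiplicity
correction is applied; p-values are reported uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .morphology import Segmentation
from .volume_io import Mask

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "smoking", "bp", "time_of_day")
ADJUST_SCALE_ML = 100.0  # burden reported per 100 mL of WM
PROGRESSION_CUTOFF_PCT = 1.8  # % brain-volume decrease over 52 weeks


@dataclass
class BurdenRecord:
    """PVS burden for one scan, raw and WM-adjusted."""

    subject: str
    timepoint: str
    cluster_count: int
    pvs_volume: int  # voxels
    wm_volume_mm3: float
    adjusted_count: float  # clusters per 100 mL WM
    adjusted_volume: float  # voxels per 100 mL WM


def compute_burden(
    seg: Segmentation, wm: Mask, subject: str = "", timepoint: str = "baseline"
) -> BurdenRecord:
    """Extract burden metrics from accepted clusters, adjusted by WM volume."""
    if wm.count == 0:
        raise ValueError("WM mask is empty; cannot adjust burden")
    wm_mm3 = wm.volume_mm3()
    wm_ml = wm_mm3 / 1000.0
    count = seg.cluster_count
    volume = seg.pvs_volume_voxels
    return BurdenRecord(
        subject=subject,
        timepoint=timepoint,
        cluster_count=count,
        pvs_volume=volume,
        wm_volume_mm3=wm_mm3,
        adjusted_count=count / wm_ml * ADJUST_SCALE_ML,
        adjusted_volume=volume / wm_ml * ADJUST_SCALE_ML,
    )


def brain_volume_change(gm_bl: float, wm_bl: float, gm_fu: float, wm_fu: float) -> float:
    """Percent change in brain volume (GM+WM) from baseline to follow-up."""
    base = gm_bl + wm_bl
    if base <= 0:
        raise ValueError("baseline brain volume must be positive")
    return 100.0 * ((gm_fu + wm_fu) - base) / base


def classify_progression(pct_change: float) -> str:
    """Label a subject from their 52-week brain-volume percent change.

    Non-progressor iff the decrease is < 1.8% (pct_change > −1.8);
    a decrease of exactly 1.8% counts as progression.
    """
    if not np.isfinite(pct_change):
        raise ValueError("percent change must be finite")
    return "non_progressor" if pct_change > -PROGRESSION_CUTOFF_PCT else "progressor"


def weighted_group_mean(group_means: list[tuple[float, int]]) -> float:
    """Whole-group mean from subgroup (mean, n) pairs: Σ mᵢnᵢ / Σ nᵢ."""
    if not group_means:
        raise ValueError("no subgroup means supplied")
    if any(n < 1 for _, n in group_means):
        raise ValueError("every subgroup must have n >= 1")
    total = sum(n for _, n in group_means)
    return sum(m * n for m, n in group_means) / total


# ---------------------------------------------------------------------------
# Association models
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Fixed-effect estimate for one outcome ~ predictor association."""

    outcome: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_subjects: int
    converged: bool = True
    method: str = "mixed"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")

    def summary(self) -> str:
        return (
            f"{self.outcome} ~ {self.predictor} [{self.method}]: "
            f"beta = {self.beta:.4g}, 95% CI [{self.ci_low:.4g}, {self.ci_high:.4g}], "
            f"p = {self.p_value:.4g} (n_obs={self.n_obs}, n_subjects={self.n_subjects}"
            f"{'' if self.converged else ', NOT CONVERGED'})"
        )


def _check_columns(data: pd.DataFrame, cols: list[str]) -> None:
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"missing columns: {missing_cols}")
    na = data[cols].isna()
    if na.any().any():
        rows = data.index[na.any(axis=1)].tolist()
        raise ValueError(f"missing values in {cols} at rows {rows[:20]}")


def _standardize(data: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    out = data.copy()
    for c in covariates:
        sd = out[c].std(ddof=0)
        if sd > 0:
            out[c] = (out[c] - out[c].mean()) / sd
        else:
            logger.warning("covariate %r is constant; centered to zero", c)
            out[c] = 0.0
    return out


def fit_mixed_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group: str = "subject",
) -> ModelResult:
    """Linear mixed model: outcome ~ predictor + covariates + (1 | subject).

    Covariates are standardized (the predictor is left on its raw scale so
    the slope keeps its natural units); fitting is by REML and the
    predictor's Wald 95% CI and p-value are returned. Singular or
    non-converged fits are flagged on the result, never silently dropped.
    """
    cols = [outcome, predictor, *covariates, group]
    _check_columns(data, cols)
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 subjects for a random-intercept model")
    if data[predictor].std(ddof=0) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    work = _standardize(data[cols].copy(), covariates)
    exog = sm.add_constant(work[[predictor, *covariates]])
    model = sm.MixedLM(work[outcome].to_numpy(), exog, groups=work[group])
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(reml=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular mixed-model fit for {outcome} ~ {predictor}: {exc}; "
            "the data cannot identify the random-intercept model"
        ) from exc
    ci = fit.conf_int().loc[predictor]
    return ModelResult(
        outcome=outcome,
        predictor=predictor,
        beta=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[predictor]),
        n_obs=int(len(work)),
        n_subjects=int(work[group].nunique()),
        converged=bool(fit.converged),
        method="mixed",
    )


def change_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group: str = "subject",
    visit_col: str = "visit",
    baseline: str = "baseline",
    followup: str = "week52",
) -> ModelResult:
    """Within-subject change analysis: Δoutcome ~ Δpredictor + covariates.

    Week-52 minus baseline deltas are computed per subject (subjects
    missing a visit are excluded with a logged count; time-varying
    covariates enter at their baseline value) and fitted by OLS — with one
    delta per subject a random intercept is not identifiable.
    """
    _check_columns(data, [outcome, predictor, group, visit_col])
    wide_counts = data.groupby(group)[visit_col].nunique()
    complete = wide_counts[wide_counts >= 2].index
    dropped = wide_counts.size - len(complete)
    if dropped:
        logger.info("excluded %d subjects missing a visit", dropped)
    if len(complete) == 0:
        raise ValueError("no subject has both visits; cannot compute changes")
    sub = data[data[group].isin(complete)]
    bl = sub[sub[visit_col] == baseline].set_index(group)
    fu = sub[sub[visit_col] == followup].set_index(group)
    deltas = pd.DataFrame(
        {
            "d_outcome": fu[outcome] - bl[outcome],
            "d_predictor": fu[predictor] - bl[predictor],
            **{c: bl[c] for c in covariates},
        }
    ).dropna()
    if len(deltas) < 3:
        raise ValueError("need at least 3 subjects with complete paired data")
    if deltas["d_predictor"].std(ddof=0) == 0:
        raise ValueError("change in predictor has zero variance")
    work = _standardize(deltas, covariates)
    exog = sm.add_constant(work[["d_predictor", *covariates]])
    fit = sm.OLS(work["d_outcome"].to_numpy(), exog).fit()
    ci = fit.conf_int().loc["d_predictor"]
    return ModelResult(
        outcome=f"change_{outcome}",
        predictor=f"change_{predictor}",
        beta=float(fit.params["d_predictor"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["d_predictor"]),
        n_obs=int(len(work)),
        n_subjects=int(len(work)),
        converged=True,
        method="ols-change",
    )


# ---------------------------------------------------------------------------
# Non-parametric tests
# ---------------------------------------------------------------------------

def paired_test(baseline, followup) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired visits.

    Zero differences are dropped; the exact distribution is used for
    n <= 25 pairs.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape:
        raise ValueError("paired samples must have equal length")
    if len(baseline) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = followup - baseline
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if len(nonzero) <= 25 else "auto"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_test(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.std(np.concatenate([a, b])) == 0:
        raise ValueError("all observations identical")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rank_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
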