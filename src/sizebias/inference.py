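"""Group-level statistics for the retained, sign-corrected cohort.

Medians with Wilcoxon signed-rank tests per condition; the additivity
comparison between the *direct* bias (Balls condition) and the *indirect*
bias (each participant's Soccer minus Tennis bias, which cancels the grey
disc's contribution if the biases add); weighted orthogonal (Deming)
regression between conditions with bootstrap slope CIs; Pearson
correlations; and the exploratory precision-vs-age linear trend per
recruitment group.

Orthogonal rather than ordinary regression because both plotted variables
are estimates with comparable measurement error, and both are in the same
units (percent of the reference size), so perpendicular distances need no
standardisation.  Each participant's weight is 1 / sqrt(Lx^2 + Ly^2) with L
the length of the bias CI on each axis, so noisy participants count less.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc import ParticipantRecord

__all__ = [
    "ConditionSummary",
    "AdditivityResult",
    "OrthogonalRegression",
    "OrthogonalRegressionResults",
    "AgeTrend",
    "wilcoxon_signed_rank",
    "condition_summary",
    "compute_additivity",
    "participant_weight",
    "weighted_orthogonal_regression",
    "bootstrap_slope_ci",
    "pearson_correlation",
    "precision_age_trend",
    "retained",
]

logger = logging.getLogger(__name__)

#: Floor on the summed squared CI lengths when both CIs are degenerate, so
#: the weight stays finite.
_MIN_SUMSQ = 1e-6


def retained(records: list[ParticipantRecord]) -> list[ParticipantRecord]:
    return [r for r in records if not r.excluded]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(values, null_center: float = 0.0) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of ``values`` against a center.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 when the absolute differences are tie-free; otherwise the normal
    approximation with continuity correction.
    """
    d = np.asarray(values, dtype=float) - null_center
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# per-condition summaries and additivity
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    condition: str
    median_bias: float
    wilcoxon_statistic: float
    p_value: float
    n: int


def condition_summary(records: list[ParticipantRecord], condition: str) -> ConditionSummary:
    """Median bias of the retained cohort in one condition, with a Wilcoxon
    test against zero.  Expects sign-corrected, QC'd records."""
    cohort = retained(records)
    if not cohort:
        raise ValueError("empty cohort")
    biases = np.array([r.fits[condition].mu_hat for r in cohort])
    stat, p = wilcoxon_signed_rank(biases, 0.0)
    return ConditionSummary(
        condition=condition,
        median_bias=float(np.median(biases)),
        wilcoxon_statistic=stat,
        p_value=p,
        n=len(biases),
    )


@dataclass
class AdditivityResult:
    """Direct (Balls) vs. indirect (Soccer - Tennis) bias comparison.

    If biases add, the grey disc's contribution cancels in the indirect
    difference and direct == indirect per participant; a systematic
    difference would indicate super-additivity of the direct comparison.
    """

    participant_ids: list[str]
    direct: np.ndarray
    indirect: np.ndarray
    median_direct: float
    median_indirect: float
    paired_statistic: float
    paired_p: float

    @property
    def n(self) -> int:
        return len(self.direct)


def compute_additivity(records: list[ParticipantRecord]) -> AdditivityResult:
    """Per-participant direct and indirect biases plus the paired Wilcoxon
    test of their difference.  Participants missing any of the three
    ball-related fits are dropped from this analysis (logged)."""
    ids, direct, indirect = [], [], []
    for rec in retained(records):
        if not {"Balls", "Soccer", "Tennis"} <= set(rec.fits):
            logger.warning("%s lacks ball-related fits; dropped from additivity", rec.participant_id)
            continue
        ids.append(rec.participant_id)
        direct.append(rec.fits["Balls"].mu_hat)
        indirect.append(rec.fits["Soccer"].mu_hat - rec.fits["Tennis"].mu_hat)
    direct_a, indirect_a = np.array(direct), np.array(indirect)
    if len(direct_a) == 0:
        raise ValueError("no participants with complete ball-related fits")
    diff = direct_a - indirect_a
    if np.all(diff == 0):
        stat, p = float("nan"), 1.0
    else:
        stat, p = wilcoxon_signed_rank(diff, 0.0)
    return AdditivityResult(
        participant_ids=ids,
        direct=direct_a,
        indirect=indirect_a,
        median_direct=float(np.median(direct_a)),
        median_indirect=float(np.median(indirect_a)),
        paired_statistic=stat,
        paired_p=p,
    )


# ---------------------------------------------------------------------------
# weighted orthogonal (Deming) regression
# ---------------------------------------------------------------------------

def participant_weight(fit_x, fit_y) -> float:
    """w = 1 / sqrt(Lx^2 + Ly^2), L = length of each bias CI.

    Accepts PsychometricFit objects or (lo, hi) tuples.  Degenerate
    (zero-length) CI pairs get a capped weight rather than infinity.
    """
    ci_x = fit_x.mu_ci if hasattr(fit_x, "mu_ci") else fit_x
    ci_y = fit_y.mu_ci if hasattr(fit_y, "mu_ci") else fit_y
    lx = ci_x[1] - ci_x[0]
    ly = ci_y[1] - ci_y[0]
    if not (math.isfinite(lx) and math.isfinite(ly)):
        raise ValueError("confidence intervals must be finite")
    sumsq = lx * lx + ly * ly
    if sumsq < _MIN_SUMSQ:
        logger.warning("zero-length CIs; weight capped")
        sumsq = _MIN_SUMSQ
    return 1.0 / math.sqrt(sumsq)


class OrthogonalRegression:
    """Weighted orthogonal regression of y on x (Deming, error-variance
    ratio 1): minimises the weighted sum of squared perpendicular distances
    to the line.

    Solved in closed form via the principal axis of the weighted covariance:
    the line passes through the weighted centroid with slope

        (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy).
    """

    def __init__(self, x, y, weights=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 points")
        if weights is None:
            weights = np.ones(len(self.x))
        self.weights = np.asarray(weights, dtype=float)
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and finite")

    def fit(self) -> "OrthogonalRegressionResults":
        w = self.weights / self.weights.sum()
        xbar = float(w @ self.x)
        ybar = float(w @ self.y)
        dx, dy = self.x - xbar, self.y - ybar
        s_xx = float(w @ (dx * dx))
        s_yy = float(w @ (dy * dy))
        s_xy = float(w @ (dx * dy))
        if s_xx == 0 and s_yy == 0:
            raise ValueError("all points identical; regression degenerate")
        if s_xy == 0:
            # principal axis aligned with a coordinate axis
            slope = 0.0 if s_xx >= s_yy else float("inf")
        else:
            slope = (s_yy - s_xx + math.hypot(s_yy - s_xx, 2 * s_xy)) / (2 * s_xy)
        intercept = ybar - slope * xbar if math.isfinite(slope) else float("nan")
        return OrthogonalRegressionResults(model=self, slope=slope, intercept=intercept)

    def objective(self, slope: float, intercept: float) -> float:
        """Weighted sum of squared perpendicular distances (normalised
        weights), for diagnostics and brute-force cross-checks."""
        w = self.weights / self.weights.sum()
        d = (self.y - intercept - slope * self.x) / math.sqrt(1 + slope * slope)
        return float(w @ (d * d))


@dataclass
class OrthogonalRegressionResults:
    model: OrthogonalRegression
    slope: float
    intercept: float
    slope_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return len(self.model.x)

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    def bootstrap_slope_ci(
        self, reps: int = 1000, level: float = 0.95, seed: int | np.random.Generator | None = None
    ) -> tuple[float, float]:
        """Percentile CI of the slope from resampling participants (points
        and their weights together) with replacement."""
        rng = np.random.default_rng(seed)
        m = self.model
        n = len(m.x)
        slopes = np.empty(reps)
        for b in range(reps):
            idx = rng.integers(0, n, size=n)
            try:
                slopes[b] = OrthogonalRegression(m.x[idx], m.y[idx], m.weights[idx]).fit().slope
            except ValueError:  # degenerate resample
                slopes[b] = np.nan
            # guard: < 3 distinct points cannot happen here (n >= 3 draws), but
            # identical points can; drop those replicates
        slopes = slopes[np.isfinite(slopes)]
        alpha = 1 - level
        lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        self.slope_ci = (float(lo), float(hi))
        return self.slope_ci

    def summary(self) -> str:
        lines = [
            "Weighted orthogonal (Deming) regression",
            "-" * 40,
            f"{'n points':<22}{self.n:>18d}",
            f"{'slope':<22}{self.slope:>18.4f}",
            f"{'intercept':<22}{self.intercept:>18.4f}",
        ]
        if self.slope_ci is not None:
            lines.append(f"{'slope 95% CI':<22}[{self.slope_ci[0]:>8.4f}, {self.slope_ci[1]:>7.4f}]")
        return "\n".join(lines)


def weighted_orthogonal_regression(x, y, weights=None) -> OrthogonalRegressionResults:
    """Functional wrapper over :class:`OrthogonalRegression`."""
    return OrthogonalRegression(x, y, weights).fit()


def bootstrap_slope_ci(x, y, weights=None, reps: int = 1000, seed=None) -> tuple[float, float]:
    """Bootstrap slope CI without keeping the results object around."""
    return weighted_orthogonal_regression(x, y, weights).bootstrap_slope_ci(reps=reps, seed=seed)


def pearson_correlation(x, y) -> float:
    """Unweighted product-moment correlation across participants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a variable is constant")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# exploratory precision-vs-age trend
# ---------------------------------------------------------------------------

@dataclass
class AgeTrend:
    group: str
    slope: float  # %/year; negative = precision improves with age
    slope_ci_halfwidth: float
    intercept: float
    n: int


def precision_age_trend(records: list[ParticipantRecord], group: str) -> AgeTrend:
    """OLS line of mean precision (sigma averaged over the four conditions)
    against age for one recruitment group, with the 95% CI half-width of the
    slope.  With fewer than 3 participants the CI is undefined (NaN)."""
    cohort = [r for r in retained(records) if r.group == group]
    if len(cohort) < 2:
        raise ValueError(f"need >= 2 retained participants in group {group!r}")
    ages = np.array([r.age for r in cohort])
    prec = np.array([np.mean([f.sigma_hat for f in r.fits.values()]) for r in cohort])
    X = sm.add_constant(ages)
    fit = sm.OLS(prec, X).fit()
    if len(cohort) == 2:
        halfwidth = float("nan")
    else:
        ci = fit.conf_int(alpha=0.05)
        halfwidth = float((ci[1, 1] - ci[1, 0]) / 2)
    return AgeTrend(
        group=group,
        slope=float(fit.params[1]),
        slope_ci_halfwidth=halfwidth,
        intercept=float(fit.params[0]),
        n=len(cohort),
    )
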