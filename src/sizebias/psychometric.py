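"""Maximum-likelihood cumulative-Gaussian psychometric fitting for 2AFC data.

The model: on a trial with signed size difference ``x`` (test minus
reference, % of the reference) the probability of judging the test larger is

    P(x) = Phi((x - mu) / sigma)

with ``mu`` the bias (point of subjective equality) and ``sigma`` the
precision (Weber fraction), both in percent.  Guess and lapse asymptotes are
fixed at exactly 0 and 1.  Responses at the same level are exchangeable, so
the Bernoulli likelihood aggregates to binomial counts per level; the
negative log-likelihood is

    NLL(mu, sigma) = -sum_i [ k_i log P(x_i) + (n_i - k_i) log(1 - P(x_i)) ]

with probabilities clipped to [1e-9, 1 - 1e-9] for finiteness.

``PsychometricModel`` holds the aggregated counts and ``fit()`` returns a
``PsychometricResults`` carrying the estimates, convergence state and
log-likelihood; ``bootstrap_ci()`` attaches percentile confidence intervals
from parametric (binomial resampling at each level under the fitted curve)
or nonparametric (trial resampling) bootstrap.  Bootstrap refits run as a
single vectorised Fisher-scoring pass across all replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "FitSettings",
    "PsychometricFit",
    "PsychometricModel",
    "PsychometricResults",
    "negative_log_likelihood",
    "fit_psychometric",
    "bootstrap_cis",
    "fit_pooled_weber",
]

_EPS = 1e-9
#: Relative slack used to decide whether an estimate sits on a bound.
_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class FitSettings:
    """Estimation and bootstrap configuration.

    Bounds are wide enough to be non-binding for sane data while keeping
    degenerate fits finite; a fit that lands on a bound is flagged
    non-converged and left to the cohort-level CI-width exclusion.
    """

    mu_bounds: tuple[float, float] = (-50.0, 50.0)
    sigma_bounds: tuple[float, float] = (0.05, 100.0)
    bootstrap_reps: int = 1000
    bootstrap_kind: Literal["parametric", "nonparametric"] = "parametric"
    ci_level: float = 0.95
    seed: int | None = None
    #: Points per axis of the coarse initialisation grid.
    grid_points: int = 21

    def __post_init__(self) -> None:
        if not (self.mu_bounds[0] < self.mu_bounds[1] and self.sigma_bounds[0] < self.sigma_bounds[1]):
            raise ValueError("bounds must be ordered")
        if self.sigma_bounds[0] <= 0:
            raise ValueError("sigma lower bound must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class PsychometricFit:
    """Flat record of one participant x condition fit (CSV-friendly)."""

    participant_id: str
    condition: str
    mu_hat: float
    sigma_hat: float
    mu_ci: tuple[float, float] | None
    sigma_ci: tuple[float, float] | None
    n_trials: int
    converged: bool
    log_likelihood: float


def _aggregate(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels, inverse = np.unique(x, return_inverse=True)
    n = np.bincount(inverse, minlength=len(levels)).astype(float)
    k = np.bincount(inverse, weights=y.astype(float), minlength=len(levels))
    return levels, k, n


def negative_log_likelihood(responses, mu: float, sigma: float) -> float:
    """Bernoulli NLL of a response set under the cumulative-Gaussian model.

    ``responses`` is anything ``PsychometricModel.from_responses`` accepts
    (a DataFrame with ``size_diff_pct`` / ``test_judged_larger``, or a pair
    of arrays).
    """
    model = PsychometricModel.from_responses(responses)
    return model.nll(mu, sigma)


class PsychometricModel:
    """Cumulative-Gaussian 2AFC model on aggregated binomial counts.

    Parameters
    ----------
    x : array of size-difference levels (%)
    k : successes ("test judged larger") per level
    n : trials per level
    """

    def __init__(self, x, k, n):
        self.x = np.asarray(x, dtype=float)
        self.k = np.asarray(k, dtype=float)
        self.n = np.asarray(n, dtype=float)
        if not (self.x.shape == self.k.shape == self.n.shape):
            raise ValueError("x, k, n must have matching shapes")
        if self.x.size == 0 or self.n.sum() == 0:
            raise ValueError("empty response set")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("need 0 <= k <= n at every level")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        x_col: str = "size_diff_pct",
        y_col: str = "test_judged_larger",
    ) -> "PsychometricModel":
        x = trials[x_col].to_numpy(dtype=float)
        y = trials[y_col].to_numpy(dtype=bool)
        return cls(*_aggregate(x, y))

    @classmethod
    def from_responses(cls, responses) -> "PsychometricModel":
        if isinstance(responses, PsychometricModel):
            return responses
        if isinstance(responses, pd.DataFrame):
            return cls.from_trials(responses)
        x, y = responses
        return cls(*_aggregate(np.asarray(x, dtype=float), np.asarray(y)))

    # -- likelihood ------------------------------------------------------

    @property
    def nobs(self) -> int:
        return int(self.n.sum())

    def predict(self, x, mu: float, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return ndtr((np.asarray(x, dtype=float) - mu) / sigma)

    def nll(self, mu: float, sigma: float) -> float:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        p = np.clip(self.predict(self.x, mu, sigma), _EPS, 1 - _EPS)
        return float(-(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)).sum())

    def _nll_grad(self, mu: float, sigma: float) -> np.ndarray:
        z = (self.x - mu) / sigma
        p = np.clip(ndtr(z), _EPS, 1 - _EPS)
        phi = norm.pdf(z)
        r = (self.k - self.n * p) / (p * (1 - p)) * phi
        # dz/dmu = -1/sigma, dz/dsigma = -z/sigma
        return np.array([r.sum() / sigma, (r * z).sum() / sigma])

    # -- estimation ------------------------------------------------------

    def _grid_start(self, settings: FitSettings) -> tuple[float, float]:
        g = settings.grid_points
        mus = np.linspace(*settings.mu_bounds, g)
        sigmas = np.geomspace(*settings.sigma_bounds, g)
        z = (self.x[None, None, :] - mus[:, None, None]) / sigmas[None, :, None]
        p = np.clip(ndtr(z), _EPS, 1 - _EPS)
        nll = -(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        return float(mus[i]), float(sigmas[j])

    def fit(self, settings: FitSettings | None = None) -> "PsychometricResults":
        """Bounded quasi-Newton MLE from the best point of a coarse grid."""
        settings = settings or FitSettings()
        start = self._grid_start(settings)
        res = optimize.minimize(
            lambda th: self.nll(th[0], th[1]),
            x0=np.array(start),
            jac=lambda th: self._nll_grad(th[0], th[1]),
            method="L-BFGS-B",
            bounds=[settings.mu_bounds, settings.sigma_bounds],
        )
        mu_hat, sigma_hat = float(res.x[0]), float(res.x[1])
        pinned = _at_bounds(mu_hat, settings.mu_bounds) or _at_bounds(sigma_hat, settings.sigma_bounds)
        return PsychometricResults(
            model=self,
            mu=mu_hat,
            sigma=sigma_hat,
            converged=bool(res.success) and not pinned,
            llf=-float(res.fun),
            settings=settings,
        )


def _at_bounds(value: float, bounds: tuple[float, float]) -> bool:
    span = bounds[1] - bounds[0]
    return value <= bounds[0] + _BOUND_TOL * span or value >= bounds[1] - _BOUND_TOL * span


@dataclass
class PsychometricResults:
    """Fit results; CIs appear after :meth:`bootstrap_ci` is called."""

    model: PsychometricModel
    mu: float
    sigma: float
    converged: bool
    llf: float
    settings: FitSettings
    mu_ci: tuple[float, float] | None = None
    sigma_ci: tuple[float, float] | None = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, x):
        return self.model.predict(x, self.mu, self.sigma)

    def bootstrap_ci(
        self,
        reps: int | None = None,
        kind: str | None = None,
        level: float | None = None,
        seed: int | np.random.Generator | None = None,
    ) -> "PsychometricResults":
        """Attach percentile bootstrap CIs for mu and sigma (in place).

        Parametric: binomial counts redrawn at each level from the fitted
        curve.  Nonparametric: trials resampled with replacement (level
        totals become multinomial).  Each replicate is refitted under the
        same bounds; seeded and reproducible.
        """
        s = self.settings
        reps = reps if reps is not None else s.bootstrap_reps
        kind = kind if kind is not None else s.bootstrap_kind
        level = level if level is not None else s.ci_level
        rng = np.random.default_rng(s.seed if seed is None else seed)

        m = self.model
        if kind == "parametric":
            p_hat = np.clip(self.predict(m.x), _EPS, 1 - _EPS)
            K = rng.binomial(m.n.astype(int), p_hat, size=(reps, len(m.x))).astype(float)
            N = np.broadcast_to(m.n, (reps, len(m.x))).astype(float)
        elif kind == "nonparametric":
            cells = np.concatenate([m.k, m.n - m.k])  # successes then failures per level
            draws = rng.multinomial(m.nobs, cells / cells.sum(), size=reps).astype(float)
            K = draws[:, : len(m.x)]
            N = K + draws[:, len(m.x) :]
        else:
            raise ValueError(f"unknown bootstrap kind: {kind!r}")

        mu_b, sigma_b = _fit_binomial_batch(m.x, K, N, s, start=(self.mu, self.sigma))
        alpha = 1 - level
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        self.mu_ci = tuple(np.percentile(mu_b, [lo, hi]))
        self.sigma_ci = tuple(np.percentile(sigma_b, [lo, hi]))
        return self

    def to_fit(self, participant_id: str = "", condition: str = "") -> PsychometricFit:
        return PsychometricFit(
            participant_id=participant_id,
            condition=condition,
            mu_hat=self.mu,
            sigma_hat=self.sigma,
            mu_ci=self.mu_ci,
            sigma_ci=self.sigma_ci,
            n_trials=self.nobs,
            converged=self.converged,
            log_likelihood=self.llf,
        )

    def summary(self) -> str:
        lines = [
            "Cumulative-Gaussian 2AFC fit",
            "-" * 40,
            f"{'n trials':<22}{self.nobs:>18d}",
            f"{'log-likelihood':<22}{self.llf:>18.4f}",
            f"{'converged':<22}{str(self.converged):>18}",
            f"{'bias mu (%)':<22}{self.mu:>18.3f}",
            f"{'precision sigma (%)':<22}{self.sigma:>18.3f}",
        ]
        if self.mu_ci is not None:
            lines.append(f"{'mu 95% CI':<22}[{self.mu_ci[0]:>8.3f}, {self.mu_ci[1]:>7.3f}]")
        if self.sigma_ci is not None:
            lines.append(f"{'sigma 95% CI':<22}[{self.sigma_ci[0]:>8.3f}, {self.sigma_ci[1]:>7.3f}]")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# batched refitting (bootstrap workhorse)
# ---------------------------------------------------------------------------

def _batch_nll(x, K, N, mu, log_sigma):
    z = (x[None, :] - mu[:, None]) * np.exp(-log_sigma)[:, None]
    p = np.clip(ndtr(z), _EPS, 1 - _EPS)
    return -(K * np.log(p) + (N - K) * np.log1p(-p)).sum(axis=1)


def _fit_binomial_batch(
    x: np.ndarray,
    K: np.ndarray,
    N: np.ndarray,
    settings: FitSettings,
    start: tuple[float, float],
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every row of (K, N) at once by damped Fisher scoring on
    (mu, log sigma), started from the original estimate.

    Score and expected information use the binomial GLM identities for
    p = Phi(z), z = (x - mu) e^{-s}: dz/dmu = -e^{-s}, dz/ds = -z.  Estimates
    are clipped to the fitting bounds each step; rows that fail to reach a
    stationary point in the interior are refitted with the bounded
    quasi-Newton path.
    """
    B = K.shape[0]
    mu = np.full(B, float(np.clip(start[0], *settings.mu_bounds)))
    s = np.full(B, float(np.log(np.clip(start[1], *settings.sigma_bounds))))
    s_lo, s_hi = np.log(settings.sigma_bounds[0]), np.log(settings.sigma_bounds[1])
    nll = _batch_nll(x, K, N, mu, s)

    for _ in range(max_iter):
        inv_sig = np.exp(-s)
        z = (x[None, :] - mu[:, None]) * inv_sig[:, None]
        p = np.clip(ndtr(z), _EPS, 1 - _EPS)
        phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        v = p * (1 - p)
        resid = (K - N * p) * phi / v  # score weight per cell
        w = N * phi**2 / v  # Fisher weight per cell

        # gradient of NLL wrt (mu, s); dz/dmu = -inv_sig, dz/ds = -z
        g_mu = (resid * inv_sig[:, None]).sum(axis=1)
        g_s = (resid * z).sum(axis=1)
        i_mm = (w * inv_sig[:, None] ** 2).sum(axis=1)
        i_ms = (w * z * inv_sig[:, None]).sum(axis=1)
        i_ss = (w * z**2).sum(axis=1)

        det = i_mm * i_ss - i_ms**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        # Newton step: theta <- theta - I^{-1} grad
        d_mu = -(i_ss * g_mu - i_ms * g_s) / det
        d_s = -(i_mm * g_s - i_ms * g_mu) / det
        d_mu = np.nan_to_num(d_mu)
        d_s = np.nan_to_num(d_s)

        # damped step: halve until the NLL does not increase
        step = np.ones(B)
        accepted = np.zeros(B, dtype=bool)
        mu_new, s_new, nll_new = mu.copy(), s.copy(), nll.copy()
        for _halve in range(12):
            trial_mu = np.clip(mu + step * d_mu, *settings.mu_bounds)
            trial_s = np.clip(s + step * d_s, s_lo, s_hi)
            trial_nll = _batch_nll(x, K, N, trial_mu, trial_s)
            better = ~accepted & (trial_nll <= nll + 1e-12)
            mu_new[better], s_new[better], nll_new[better] = (
                trial_mu[better],
                trial_s[better],
                trial_nll[better],
            )
            accepted |= better
            if accepted.all():
                break
            step *= 0.5

        moved = np.abs(mu_new - mu) + np.abs(s_new - s)
        mu, s, nll = mu_new, s_new, nll_new
        if np.all(moved < tol):
            break

    sigma = np.exp(s)

    # fallback: rows stuck in the interior with a non-trivial gradient
    inv_sig = np.exp(-s)
    z = (x[None, :] - mu[:, None]) * inv_sig[:, None]
    p = np.clip(ndtr(z), _EPS, 1 - _EPS)
    phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    resid = (K - N * p) * phi / (p * (1 - p))
    grad_norm = np.abs((resid * inv_sig[:, None]).sum(axis=1)) + np.abs((resid * z).sum(axis=1))
    interior = (
        (mu > settings.mu_bounds[0] + 1e-9)
        & (mu < settings.mu_bounds[1] - 1e-9)
        & (sigma > settings.sigma_bounds[0] * (1 + 1e-9))
        & (sigma < settings.sigma_bounds[1] * (1 - 1e-9))
    )
    for idx in np.nonzero(interior & (grad_norm > 1e-4))[0]:
        res = PsychometricModel(x, K[idx], np.maximum(N[idx], 0)).fit(settings)
        mu[idx], sigma[idx] = res.mu, res.sigma

    return mu, sigma


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_psychometric(responses, settings: FitSettings | None = None) -> PsychometricResults:
    """MLE fit of one response set (see :class:`PsychometricModel`)."""
    model = PsychometricModel.from_responses(responses)
    if len(model.x) < 2:
        raise ValueError("need responses at >= 2 distinct size levels")
    return model.fit(settings)


def bootstrap_cis(
    responses,
    fit: PsychometricResults,
    settings: FitSettings | None = None,
    seed=None,
) -> PsychometricResults:
    """Attach bootstrap CIs to an existing fit (wrapper over
    :meth:`PsychometricResults.bootstrap_ci`)."""
    if settings is not None:
        fit = replace(fit, settings=settings)
    return fit.bootstrap_ci(seed=seed)


def fit_pooled_weber(trials: pd.DataFrame, settings: FitSettings | None = None) -> float:
    """Pooled Weber fraction: a single fit to all of a participant's trials
    merged across conditions (raw response axis); returns sigma-hat (%)."""
    if len(trials) == 0:
        raise ValueError("no trials to pool")
    return fit_psychometric(PsychometricModel.from_trials(trials), settings).sigma
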