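"""Figure helpers: psychometric curves, bias/precision scatters, additivity.

Each function draws on a provided (or fresh) matplotlib Axes and returns it,
so figures compose; nothing here is required by the numerical pipeline.
"""

from __future__ import annotations

import numpy as np

from . import inference
from .psychometric import PsychometricResults


def plot_psychometric(results: PsychometricResults, ax=None, n_grid: int = 200):
    """Data proportions and fitted curve for one participant x condition."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    m = results.model
    ax.plot(m.x, m.k / np.maximum(m.n, 1), "o", color="k", label="data")
    grid = np.linspace(m.x.min(), m.x.max(), n_grid)
    ax.plot(grid, results.predict(grid), "-", color="tab:blue", label="fit")
    ax.axvline(results.mu, color="tab:blue", lw=0.8)
    if results.mu_ci is not None:
        ax.plot(results.mu_ci, [0.5, 0.5], color="tab:blue", lw=2, alpha=0.5)
    ax.set_xlabel("size difference (%)")
    ax.set_ylabel("P(test judged larger)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_bias_scatter(records, cond_x: str, cond_y: str, ax=None, regression=True):
    """Per-participant biases in one condition against another, with CIs,
    the identity line and (optionally) the weighted orthogonal fit."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    cohort = inference.retained(records)
    x = np.array([r.fits[cond_x].mu_hat for r in cohort])
    y = np.array([r.fits[cond_y].mu_hat for r in cohort])
    xerr = np.array(
        [
            [r.fits[cond_x].mu_hat - r.fits[cond_x].mu_ci[0] for r in cohort],
            [r.fits[cond_x].mu_ci[1] - r.fits[cond_x].mu_hat for r in cohort],
        ]
    )
    yerr = np.array(
        [
            [r.fits[cond_y].mu_hat - r.fits[cond_y].mu_ci[0] for r in cohort],
            [r.fits[cond_y].mu_ci[1] - r.fits[cond_y].mu_hat for r in cohort],
        ]
    )
    ax.errorbar(x, y, xerr=np.abs(xerr), yerr=np.abs(yerr), fmt="o", ms=4, alpha=0.6, lw=0.8)
    lims = [min(x.min(), y.min()) - 1, max(x.max(), y.max()) + 1]
    ax.plot(lims, lims, "--", color="grey", lw=0.8, label="identity")
    if regression:
        w = np.array([inference.participant_weight(r.fits[cond_x], r.fits[cond_y]) for r in cohort])
        fit = inference.weighted_orthogonal_regression(x, y, w)
        grid = np.array(lims)
        ax.plot(grid, fit.intercept + fit.slope * grid, "-", color="grey", label="orthogonal fit")
    ax.set_xlabel(f"{cond_x} bias (%)")
    ax.set_ylabel(f"{cond_y} bias (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_additivity(result: inference.AdditivityResult, ax=None):
    """Indirect (Soccer - Tennis) vs. direct (Balls) bias with identity line."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(result.direct, result.indirect, "o", ms=4, alpha=0.7)
    lims = [
        min(result.direct.min(), result.indirect.min()) - 1,
        max(result.direct.max(), result.indirect.max()) + 1,
    ]
    ax.plot(lims, lims, "--", color="grey", lw=0.8)
    ax.set_xlabel("direct bias: Balls (%)")
    ax.set_ylabel("indirect bias: Soccer - Tennis (%)")
    return ax


def plot_precision_age(records, ax=None):
    """Mean precision per participant against age, split by group, with the
    per-group OLS trend line."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for group, marker in (("credit", "s"), ("volunteer", "o")):
        members = [r for r in inference.retained(records) if r.group == group]
        if not members:
            continue
        ages = np.array([r.age for r in members])
        prec = np.array([np.mean([f.sigma_hat for f in r.fits.values()]) for r in members])
        ax.plot(ages, prec, marker, ms=4, alpha=0.7, label=group)
        if len(members) >= 3 and np.all(np.isfinite(ages)):
            trend = inference.precision_age_trend(records, group)
            grid = np.linspace(ages.min(), ages.max(), 2)
            ax.plot(grid, trend.intercept + trend.slope * grid, "-", lw=1)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mean precision sigma (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax
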