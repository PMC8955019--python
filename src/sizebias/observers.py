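"""Synthetic 2AFC observers with the between-participant structure the
analysis pipeline assumes.

Each simulated observer is a lapse-free cumulative-Gaussian decision maker:
on a trial with size difference ``x`` (test minus reference, % of reference)
the test image is judged larger with probability ``Phi((x - mu) / sigma)``,
where ``mu`` is the observer's bias (point of subjective equality) and
``sigma`` the just-noticeable difference (Weber fraction), both in percent.

The cohort generator plants the structure the group analysis probes:

* per-condition population biases (assimilation for Soccer, contrast for
  Tennis and Coins under the analysis sign convention);
* a shared grey-disc component ``g_p`` added to a participant's Soccer and
  Tennis biases, inducing the correlation expected when both conditions use
  the same unfamiliar reference disc;
* exact per-participant additivity — the Balls (direct) bias equals the
  Soccer minus Tennis (indirect) bias up to a small noise term — so the
  no-super-additivity analysis has known ground truth;
* a log-normal spread of precisions, inflated for the "credit" half of the
  cohort, plus an optional linear age trend;
* a handful of deliberately bad observers (very high Weber fraction, or
  pure guessing in one condition) that the exclusion rules must catch.

Biases are stored on the *analysis* scale, on which negative always means
assimilation.  For the Coins condition the raw measurement axis points the
other way (the larger coin is the nominal reference), so response simulation
negates the Coins bias; the pipeline's sign-correction step then recovers
the planted value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import INVERTED_CONDITIONS, StudyConfig, build_trial_table, plan_blocks, shuffle_trials

__all__ = [
    "ObserverParams",
    "PopulationParams",
    "psychometric_probability",
    "sample_population",
    "simulate_responses",
    "simulate_session",
    "simulate_cohort",
    "observers_to_frame",
]

#: sigma at or above this value is treated as "pure guessing" when simulating
#: degenerate observers (response probability indistinguishable from 0.5).
GUESSING_SIGMA = 1e6


@dataclass
class ObserverParams:
    """Ground-truth parameters of one simulated participant.

    ``bias_by_condition`` uses the analysis sign convention (negative =
    assimilation); ``sigma_by_condition`` is in percent and positive.
    """

    participant_id: str
    bias_by_condition: dict[str, float]
    sigma_by_condition: dict[str, float]
    group: str = "volunteer"  # "credit" or "volunteer"
    age: float = 25.0

    def __post_init__(self) -> None:
        for cond, sigma in self.sigma_by_condition.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive (condition {cond!r}: {sigma})")


@dataclass(frozen=True)
class PopulationParams:
    """Between-participant generative model for a cohort.

    Defaults emulate the observed cohort structure: Soccer bias ~ -5%
    (assimilation), Tennis ~ +1.5% and Coins ~ +1.7% (contrast), a grey-disc
    component shared by Soccer and Tennis, near-exact additivity of the Balls
    bias, precisions spanning roughly 1.7-10.9% across 63 good observers with
    the credit group less precise, and 4 + 3 planted bad observers for the
    two exclusion rules.
    """

    condition_means: Mapping[str, float] = field(
        default_factory=lambda: {"Soccer": -5.0, "Tennis": 1.5, "Coins": 1.7}
    )
    grey_disc_sd: float = 2.0
    idiosyncratic_bias_sd: float = 1.2
    additivity_noise_sd: float = 0.5
    #: Good observers' biases are redrawn until every condition bias lies
    #: within +/- bias_cap (%), and sigma is then drawn from the log-normal
    #: truncated to |worst bias| + 2 sigma <= identifiability_margin.  A
    #: psychometric curve whose central +/-2-sigma portion extends far past
    #: the presented +/-10% range cannot be pinned down by the design: its
    #: bootstrap bias CI blows up stochastically, which would plant
    #: unidentifiable "good" observers and destroy the ground truth the
    #: exclusion tests rely on.  Rejecting biases only mildly (and
    #: truncating sigma, not the biases, against the joint margin) keeps the
    #: planted bias medians essentially undistorted while preserving exact
    #: per-participant additivity.
    bias_cap: float = 8.5
    identifiability_margin: float = 16.0
    sigma_log_mean: float = math.log(3.0)
    sigma_log_sd: float = 0.35
    group_sigma_multiplier: float = 1.55
    age_range: tuple[float, float] = (17.0, 73.0)
    #: Linear change of sigma with age, %/year (negative = precision improves
    #: with age); 0 disables the trend.
    age_precision_slope: float = 0.0
    #: Planted bad observers (always placed in the credit group).
    n_high_weber: int = 4
    n_degenerate: int = 3
    #: True sigma of the high-Weber plants.  The pooled sigma estimate has a
    #: log-scale spread of roughly 0.25 when the true value is far beyond
    #: the stimulus range, so the plant sits several of those spreads above
    #: the 20% threshold to keep its classification unambiguous.
    high_weber_sigma_range: tuple[float, float] = (35.0, 50.0)
    #: Cap on the usable-condition sigma of degenerate (guessing) observers,
    #: keeping their pooled Weber fraction safely below the exclusion
    #: threshold so only the CI-width rule catches them.
    degenerate_good_sigma_cap: float = 3.5

    def __post_init__(self) -> None:
        for name in ("grey_disc_sd", "idiosyncratic_bias_sd", "additivity_noise_sd", "sigma_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.group_sigma_multiplier <= 0:
            raise ValueError("group_sigma_multiplier must be positive")


def psychometric_probability(x, mu: float, sigma: float):
    """P(test judged larger) at size difference ``x``: Phi((x - mu) / sigma).

    Strictly increasing in ``x``; equals 1/2 at ``x = mu``.  Lapse-free, so
    the asymptotes are exactly 0 and 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndtr((np.asarray(x, dtype=float) - mu) / sigma)


def _draw_age(rng: np.random.Generator, age_range: tuple[float, float]) -> float:
    # Right-skewed ages (median in the mid-twenties for the default 17-73
    # range), matching a mostly-student cohort with an older tail.
    lo, hi = age_range
    age = lo + rng.exponential(scale=(hi - lo) / 7.0)
    return float(min(age, hi))


def sample_population(
    params: PopulationParams, n: int, seed: int | np.random.Generator
) -> list[ObserverParams]:
    """Draw ``n`` observers; seeded and reproducible.

    Per participant p (conditions on the analysis scale):

    * ``mu_Soccer = nu_Soccer + g_p + eps``; ``mu_Tennis = nu_Tennis + g_p +
      eps'`` with ``g_p ~ N(0, grey_disc_sd)`` shared between the two,
    * ``mu_Balls = mu_Soccer - mu_Tennis + N(0, additivity_noise_sd)``,
    * ``mu_Coins = nu_Coins + eps''``,
    * one sigma per participant, shared across conditions: log-normal,
      multiplied by ``group_sigma_multiplier`` for credit-group members and
      shifted by the age trend.

    The first ``n_high_weber`` credit-group members get sigma drawn from
    ``high_weber_sigma_range`` (caught by the pooled-Weber rule); the next
    ``n_degenerate`` guess at random in one condition (caught by the CI-width
    rule).  The first ``ceil(n/2)`` observers form the credit group.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nu = dict(params.condition_means)
    n_credit = (n + 1) // 2
    n_bad = params.n_high_weber + params.n_degenerate
    if n_bad > n_credit:
        raise ValueError("planted bad observers exceed the credit group size")

    width = len(str(n))
    observers: list[ObserverParams] = []
    mean_age = 0.5 * (params.age_range[0] + params.age_range[1])
    for i in range(n):
        group = "credit" if i < n_credit else "volunteer"
        age = _draw_age(rng, params.age_range)

        for _attempt in range(10_000):
            g = rng.normal(0.0, params.grey_disc_sd)
            mu_soccer = nu["Soccer"] + g + rng.normal(0.0, params.idiosyncratic_bias_sd)
            mu_tennis = nu["Tennis"] + g + rng.normal(0.0, params.idiosyncratic_bias_sd)
            mu_balls = mu_soccer - mu_tennis + rng.normal(0.0, params.additivity_noise_sd)
            mu_coins = nu["Coins"] + rng.normal(0.0, params.idiosyncratic_bias_sd)
            worst = max(abs(mu_soccer), abs(mu_tennis), abs(mu_balls), abs(mu_coins))
            if worst <= params.bias_cap:
                break
        else:  # pathological parameters: fall back to clipping the draw
            mu_soccer, mu_tennis, mu_balls, mu_coins = (
                float(np.clip(v, -params.bias_cap, params.bias_cap))
                for v in (mu_soccer, mu_tennis, mu_balls, mu_coins)
            )
            worst = params.bias_cap

        sigma_cap = max((params.identifiability_margin - worst) / 2, 0.5)
        for _attempt in range(10_000):
            sigma = float(rng.lognormal(params.sigma_log_mean, params.sigma_log_sd))
            if group == "credit":
                sigma *= params.group_sigma_multiplier
            sigma += params.age_precision_slope * (age - mean_age)
            sigma = max(sigma, 0.5)
            if sigma <= sigma_cap:
                break
        else:
            sigma = sigma_cap

        sigmas = {c: sigma for c in ("Balls", "Coins", "Soccer", "Tennis")}
        if i < params.n_high_weber:
            bad_sigma = float(rng.uniform(*params.high_weber_sigma_range))
            sigmas = {c: bad_sigma for c in sigmas}
        elif i < n_bad:
            capped = min(sigma, params.degenerate_good_sigma_cap)
            sigmas = {c: capped for c in sigmas}
            guess_cond = ("Balls", "Coins", "Soccer", "Tennis")[(i - params.n_high_weber) % 4]
            sigmas[guess_cond] = GUESSING_SIGMA

        observers.append(
            ObserverParams(
                participant_id=f"p{i + 1:0{width}d}",
                bias_by_condition={
                    "Balls": mu_balls,
                    "Coins": mu_coins,
                    "Soccer": mu_soccer,
                    "Tennis": mu_tennis,
                },
                sigma_by_condition=sigmas,
                group=group,
                age=age,
            )
        )
    return observers


def _raw_mu(observer: ObserverParams, condition: str) -> float:
    """Bias on the raw measurement axis of ``condition``.

    Conditions in INVERTED_CONDITIONS are stored sign-corrected, so the raw
    simulation axis needs the negation undone.
    """
    mu = observer.bias_by_condition[condition]
    return -mu if condition in INVERTED_CONDITIONS else mu


def simulate_responses(
    observer: ObserverParams,
    table: pd.DataFrame,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Fill the trial table's ``response`` column by Bernoulli sampling.

    Each trial's P(test judged larger) comes from the observer's psychometric
    function for that condition; the side assignment is carried through but
    never alters the probability (sides are pooled downstream).  Returns a
    copy of the table with ``response`` set to "left"/"right".
    """
    rng = np.random.default_rng(seed)
    missing = set(table["condition"].unique()) - set(observer.bias_by_condition)
    if missing:
        raise ValueError(f"observer lacks parameters for conditions: {sorted(missing)}")

    out = table.copy()
    x = out["size_diff_pct"].to_numpy(dtype=float)
    p = np.empty(len(out))
    for cond in out["condition"].unique():
        mask = (out["condition"] == cond).to_numpy()
        p[mask] = psychometric_probability(
            x[mask], _raw_mu(observer, cond), observer.sigma_by_condition[cond]
        )
    test_larger = rng.random(len(out)) < p
    test_side = out["test_side"].to_numpy()
    other = np.where(test_side == "left", "right", "left")
    out["response"] = np.where(test_larger, test_side, other)
    return out


def simulate_session(
    observer: ObserverParams,
    config: StudyConfig,
    block_order: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """One complete session: build, block, shuffle and answer the trial table."""
    seq = _as_seedseq(seed)
    s_shuffle, s_resp = seq.spawn(2)
    table = build_trial_table(config, observer.participant_id)
    table = plan_blocks(table, config, block_order=block_order)
    table = shuffle_trials(table, np.random.default_rng(s_shuffle))
    return simulate_responses(observer, table, np.random.default_rng(s_resp))


def simulate_cohort(
    params: PopulationParams,
    config: StudyConfig,
    n: int,
    seed: int,
) -> tuple[pd.DataFrame, list[ObserverParams]]:
    """Simulate a full cohort; block order alternates with recruitment index
    (even participants see the ball block first) to counterbalance.

    Returns the concatenated long-format trial table and the ground-truth
    observer list.
    """
    seq = np.random.SeedSequence(seed)
    s_pop, s_sessions = seq.spawn(2)
    observers = sample_population(params, n, np.random.default_rng(s_pop))
    session_seeds = s_sessions.spawn(n)
    frames = [
        simulate_session(obs, config, block_order=i % 2, seed=session_seeds[i])
        for i, obs in enumerate(observers)
    ]
    return pd.concat(frames, ignore_index=True), observers


def observers_to_frame(observers: Sequence[ObserverParams]) -> pd.DataFrame:
    """Ground-truth table (one row per participant x condition) for recovery
    tests and companion CSVs."""
    rows = []
    for obs in observers:
        for cond, mu in obs.bias_by_condition.items():
            rows.append(
                {
                    "participant_id": obs.participant_id,
                    "condition": cond,
                    "true_bias_pct": mu,
                    "true_sigma_pct": obs.sigma_by_condition[cond],
                    "group": obs.group,
                    "age": obs.age,
                }
            )
    return pd.DataFrame(rows)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        # derive a child sequence from the generator's stream
        return np.random.SeedSequence(int(seed.integers(0, 2**31 - 1)))
    return np.random.SeedSequence(seed)
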