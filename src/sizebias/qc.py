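"""Cohort quality control: exclusion rules and the coin sign convention.

Two rules, applied in a fixed order, remove participants whose responses are
too noisy to interpret:

1. **high_weber** — the Weber fraction fitted to the participant's *pooled*
   trials (all conditions merged) is at or above 20%, i.e. their
   discrimination noise is as large as the whole +/-10% stimulus range.
2. **wide_ci** — in at least one condition the 95% bootstrap CI of the bias
   is at least as wide as the stimulus range (20 percentage points), so the
   bias cannot be determined reliably.

A participant failing both is attributed to the Weber rule only (the CI rule
is evaluated on Weber survivors).  The same 20-point figure serves both
rules because both compare noise against the presented range of sizes.

The sign convention: the nominal reference in the Coins condition is the
2-euro coin — the *larger* familiar object, opposite to every other
condition — so Coins biases (and their CIs) are negated before group
analysis.  Afterwards a negative bias means assimilation in all conditions.
Precision is unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .design import INVERTED_CONDITIONS
from .psychometric import PsychometricFit

__all__ = [
    "ParticipantRecord",
    "ExclusionReport",
    "exclude_high_weber",
    "exclude_wide_ci",
    "apply_sign_convention",
    "run_qc",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

WEBER_THRESHOLD_PCT = 20.0
STIMULUS_RANGE_PCT = 20.0


@dataclass
class ParticipantRecord:
    """All per-participant fit output plus exclusion state."""

    participant_id: str
    fits: dict[str, PsychometricFit]
    pooled_weber: float | None
    group: str = "volunteer"
    age: float = float("nan")
    excluded: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)
    sign_corrected: bool = False

    def _flag(self, reason: str) -> None:
        if reason not in self.exclusion_reasons:
            self.exclusion_reasons.append(reason)
        self.excluded = True


@dataclass
class ExclusionReport:
    n_input: int
    n_excluded_weber: int
    n_excluded_ci: int
    n_retained: int
    reasons: dict[str, list[str]]

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + self.n_excluded_weber + self.n_excluded_ci

    def log(self) -> None:
        logger.info(
            "exclusions: %d in, %d high-Weber, %d wide-CI, %d retained",
            self.n_input,
            self.n_excluded_weber,
            self.n_excluded_ci,
            self.n_retained,
        )
        for pid, reasons in sorted(self.reasons.items()):
            logger.info("excluded %s: %s", pid, ", ".join(reasons))


def exclude_high_weber(
    records: list[ParticipantRecord], threshold: float = WEBER_THRESHOLD_PCT
) -> list[ParticipantRecord]:
    """Flag participants whose pooled Weber fraction is >= ``threshold`` (%)."""
    for rec in records:
        if rec.pooled_weber is None:
            raise ValueError(f"{rec.participant_id}: pooled Weber fraction missing")
        if rec.pooled_weber >= threshold:
            rec._flag("high_weber")
    return records


def exclude_wide_ci(
    records: list[ParticipantRecord], stimulus_range: float = STIMULUS_RANGE_PCT
) -> list[ParticipantRecord]:
    """Flag participants with any bias CI at least ``stimulus_range`` wide.

    Applied only to participants not already excluded, so the Weber rule
    takes attribution precedence.
    """
    for rec in records:
        if rec.excluded:
            continue
        for cond, fit in rec.fits.items():
            if fit.mu_ci is None:
                raise ValueError(f"{rec.participant_id}/{cond}: bias CI missing")
            lo, hi = fit.mu_ci
            if hi - lo >= stimulus_range:
                rec._flag("wide_ci")
                break
    return records


def apply_sign_convention(fits: dict[str, PsychometricFit]) -> dict[str, PsychometricFit]:
    """Negate the bias (and swap its CI endpoints) of sign-inverted
    conditions; precision and its CI are untouched.  Involution."""
    known = {"Balls", "Coins", "Soccer", "Tennis"}
    out = {}
    for cond, fit in fits.items():
        if cond not in known:
            raise ValueError(f"unknown condition label: {cond!r}")
        if cond in INVERTED_CONDITIONS:
            mu_ci = None if fit.mu_ci is None else (-fit.mu_ci[1], -fit.mu_ci[0])
            out[cond] = PsychometricFit(
                participant_id=fit.participant_id,
                condition=fit.condition,
                mu_hat=-fit.mu_hat,
                sigma_hat=fit.sigma_hat,
                mu_ci=mu_ci,
                sigma_ci=fit.sigma_ci,
                n_trials=fit.n_trials,
                converged=fit.converged,
                log_likelihood=fit.log_likelihood,
            )
        else:
            out[cond] = fit
    return out


def run_qc(
    records: list[ParticipantRecord],
    weber_threshold: float = WEBER_THRESHOLD_PCT,
    stimulus_range: float = STIMULUS_RANGE_PCT,
    sign_correct: bool = True,
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Apply both exclusion rules (Weber first) and the sign convention.

    Returns the updated records (all of them, flagged) and a reconciled
    report.  Idempotent.
    """
    unknown = {
        cond
        for rec in records
        for cond in rec.fits
        if cond not in {"Balls", "Coins", "Soccer", "Tennis"}
    }
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    exclude_high_weber(records, threshold=weber_threshold)
    n_weber = sum("high_weber" in r.exclusion_reasons for r in records)
    exclude_wide_ci(records, stimulus_range=stimulus_range)
    n_ci = sum(
        "wide_ci" in r.exclusion_reasons and "high_weber" not in r.exclusion_reasons
        for r in records
    )
    if sign_correct:
        for rec in records:
            if not rec.sign_corrected:  # keeps run_qc idempotent (negation is an involution)
                rec.fits = apply_sign_convention(rec.fits)
                rec.sign_corrected = True
    report = ExclusionReport(
        n_input=len(records),
        n_excluded_weber=n_weber,
        n_excluded_ci=n_ci,
        n_retained=len(records) - n_weber - n_ci,
        reasons={r.participant_id: list(r.exclusion_reasons) for r in records if r.excluded},
    )
    report.log()
    return records, report


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Long-format table of fits (one row per participant x condition)."""
    rows = []
    for rec in records:
        for cond, fit in rec.fits.items():
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": cond,
                    "mu_hat": fit.mu_hat,
                    "mu_ci_lo": None if fit.mu_ci is None else fit.mu_ci[0],
                    "mu_ci_hi": None if fit.mu_ci is None else fit.mu_ci[1],
                    "sigma_hat": fit.sigma_hat,
                    "sigma_ci_lo": None if fit.sigma_ci is None else fit.sigma_ci[0],
                    "sigma_ci_hi": None if fit.sigma_ci is None else fit.sigma_ci[1],
                    "n_trials": fit.n_trials,
                    "converged": fit.converged,
                    "log_likelihood": fit.log_likelihood,
                    "pooled_weber": rec.pooled_weber,
                    "group": rec.group,
                    "age": rec.age,
                    "excluded": rec.excluded,
                    "exclusion_reasons": ";".join(rec.exclusion_reasons),
                }
            )
    return pd.DataFrame(rows)
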