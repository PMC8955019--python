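"""End-to-end analysis driver: (simulate or read) -> fit -> QC -> summarise.

The pipeline is a pure function of (input, config, master seed).  All
randomness — cohort simulation, bootstrap resampling, regression bootstrap —
derives from one master seed through ``numpy.random.SeedSequence`` spawning,
so a rerun with the same config reproduces every number bit for bit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, qc
from .design import StudyConfig
from .io import read_trials_csv, write_trials_csv
from .observers import PopulationParams, observers_to_frame, simulate_cohort
from .psychometric import FitSettings, PsychometricModel, fit_pooled_weber
from .qc import ExclusionReport, ParticipantRecord, records_to_frame, run_qc

__all__ = ["PipelineConfig", "PipelineResult", "fit_cohort", "run_pipeline", "records_from_frame"]

logger = logging.getLogger(__name__)

_CONDITION_PAIRS = list(itertools.combinations(("Balls", "Coins", "Soccer", "Tennis"), 2))


@dataclass
class PipelineConfig:
    """Everything the driver needs; either an input file or simulation."""

    input_path: str | None = None
    simulate: bool = False
    n_participants: int = 70
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    weber_threshold: float = qc.WEBER_THRESHOLD_PCT
    stimulus_range: float = qc.STIMULUS_RANGE_PCT
    apply_exclusions: bool = True
    regression_reps: int = 1000
    column_map: dict | None = None
    condition_map: dict | None = None
    response_map: dict | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.input_path is None and not self.simulate:
            raise ValueError("config needs an input file or simulate=True")


@dataclass
class PipelineResult:
    records: list[ParticipantRecord]
    report: ExclusionReport
    fits: pd.DataFrame
    condition_summaries: pd.DataFrame
    additivity: inference.AdditivityResult
    additivity_frame: pd.DataFrame
    regressions: pd.DataFrame
    age_trends: pd.DataFrame
    trials: pd.DataFrame
    truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(out / "fits.csv", index=False)
        pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "reasons": ";".join(reasons),
                }
                for pid, reasons in sorted(self.report.reasons.items())
            ]
        ).to_csv(out / "exclusions.csv", index=False)
        self.condition_summaries.to_csv(out / "condition_summaries.csv", index=False)
        self.additivity_frame.to_csv(out / "additivity.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        self.age_trends.to_csv(out / "age_trends.csv", index=False)
        if self.truth is not None:
            write_trials_csv(self.trials, out / "simulated_trials.csv")
            self.truth.to_csv(out / "ground_truth.csv", index=False)


def _test_judged_larger(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    out["test_judged_larger"] = out["response"] == out["test_side"]
    return out


def fit_cohort(
    trials_by_pid: dict[str, pd.DataFrame],
    settings: FitSettings,
    seed: int,
    meta: dict[str, dict] | None = None,
) -> list[ParticipantRecord]:
    """Fit every participant x condition with bootstrap CIs, plus the pooled
    Weber fraction per participant.  ``meta`` optionally supplies group/age."""
    records = []
    pids = sorted(trials_by_pid)
    seeds = np.random.SeedSequence(seed).spawn(len(pids))
    for pid, pid_seed in zip(pids, seeds):
        trials = _test_judged_larger(trials_by_pid[pid])
        fits = {}
        cond_seeds = pid_seed.spawn(len(trials["condition"].unique()))
        for cond, cseed in zip(sorted(trials["condition"].unique()), cond_seeds):
            sub = trials[trials["condition"] == cond]
            res = PsychometricModel.from_trials(sub).fit(settings)
            res.bootstrap_ci(seed=np.random.default_rng(cseed))
            fits[cond] = res.to_fit(pid, cond)
        pooled = fit_pooled_weber(trials, settings)
        info = (meta or {}).get(pid, {})
        records.append(
            ParticipantRecord(
                participant_id=pid,
                fits=fits,
                pooled_weber=pooled,
                group=info.get("group", "volunteer"),
                age=info.get("age", float("nan")),
            )
        )
    logger.info("fitted %d participants (%d fits)", len(records), sum(len(r.fits) for r in records))
    return records


def _bias_points(records, cond_x, cond_y):
    cohort = inference.retained(records)
    x = np.array([r.fits[cond_x].mu_hat for r in cohort])
    y = np.array([r.fits[cond_y].mu_hat for r in cohort])
    w = np.array(
        [inference.participant_weight(r.fits[cond_x], r.fits[cond_y]) for r in cohort]
    )
    return x, y, w


def _regression_row(name, x, y, w, reps, rng):
    res = inference.weighted_orthogonal_regression(x, y, w)
    lo, hi = res.bootstrap_slope_ci(reps=reps, seed=rng)
    try:
        corr = inference.pearson_correlation(x, y)
    except ValueError:
        corr = float("nan")
    return {
        "pair": name,
        "slope": res.slope,
        "intercept": res.intercept,
        "slope_ci_lo": lo,
        "slope_ci_hi": hi,
        "pearson_r": corr,
        "n": res.n,
    }


def summarize_cohort(
    records: list[ParticipantRecord], regression_reps: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, inference.AdditivityResult, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All group-level tables for a QC'd, sign-corrected cohort."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    summaries = pd.DataFrame(
        [
            vars(inference.condition_summary(records, cond))
            for cond in ("Balls", "Coins", "Soccer", "Tennis")
        ]
    )

    add = inference.compute_additivity(records)
    additivity_frame = pd.DataFrame(
        {
            "participant_id": add.participant_ids,
            "direct_bias": add.direct,
            "indirect_bias": add.indirect,
        }
    )

    rows = []
    for cx, cy in _CONDITION_PAIRS:
        x, y, w = _bias_points(records, cx, cy)
        rows.append(_regression_row(f"bias:{cx}~{cy}", x, y, w, regression_reps, rng))
    # direct vs indirect (additivity scatter): the indirect CI length is the
    # two component CIs combined in quadrature
    cohort = inference.retained(records)
    w_di = []
    for r in cohort:
        lb = r.fits["Balls"].mu_ci
        ls = r.fits["Soccer"].mu_ci
        lt = r.fits["Tennis"].mu_ci
        l_dir = lb[1] - lb[0]
        l_ind_sq = (ls[1] - ls[0]) ** 2 + (lt[1] - lt[0]) ** 2
        w_di.append(1.0 / np.sqrt(max(l_dir**2 + l_ind_sq, 1e-6)))
    rows.append(
        _regression_row(
            "bias:direct~indirect", add.direct, add.indirect, np.array(w_di), regression_reps, rng
        )
    )
    # precision correlations across conditions (no regression weights needed
    # for the correlation itself)
    for cx, cy in _CONDITION_PAIRS:
        sx = np.array([r.fits[cx].sigma_hat for r in cohort])
        sy = np.array([r.fits[cy].sigma_hat for r in cohort])
        try:
            corr = inference.pearson_correlation(sx, sy)
        except ValueError:
            corr = float("nan")
        rows.append(
            {
                "pair": f"precision:{cx}~{cy}",
                "slope": float("nan"),
                "intercept": float("nan"),
                "slope_ci_lo": float("nan"),
                "slope_ci_hi": float("nan"),
                "pearson_r": corr,
                "n": len(sx),
            }
        )
    regressions = pd.DataFrame(rows)

    trend_rows = []
    for group in ("credit", "volunteer"):
        members = [r for r in inference.retained(records) if r.group == group]
        if len(members) >= 3 and all(np.isfinite(r.age) for r in members):
            trend_rows.append(vars(inference.precision_age_trend(records, group)))
        else:
            logger.info("skipping age trend for group %r (too few members or no ages)", group)
    age_trends = pd.DataFrame(trend_rows)

    return summaries, add, additivity_frame, regressions, age_trends


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and reconcile counts; see module docstring."""
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    s_sim, s_fit, s_summ = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(3))

    truth_frame = None
    if config.simulate:
        trials, observers = simulate_cohort(
            config.population, config.study, config.n_participants, s_sim
        )
        truth_frame = observers_to_frame(observers)
        trials_by_pid = {pid: g.reset_index(drop=True) for pid, g in trials.groupby("participant_id")}
        meta = {o.participant_id: {"group": o.group, "age": o.age} for o in observers}
        logger.info("simulated %d participants x %d trials", len(trials_by_pid), len(trials) // max(len(trials_by_pid), 1))
    else:
        trials_by_pid = read_trials_csv(
            config.input_path,
            column_map=config.column_map,
            condition_map=config.condition_map,
            response_map=config.response_map,
        )
        trials = pd.concat(trials_by_pid.values(), ignore_index=True)
        meta = None
        logger.info("read %d participants (%d trials)", len(trials_by_pid), len(trials))

    records = fit_cohort(trials_by_pid, config.fit_settings, s_fit, meta=meta)

    if config.apply_exclusions:
        records, report = run_qc(
            records,
            weber_threshold=config.weber_threshold,
            stimulus_range=config.stimulus_range,
        )
    else:
        records, report = run_qc(records, weber_threshold=float("inf"), stimulus_range=float("inf"))

    summaries, add, additivity_frame, regressions, age_trends = summarize_cohort(
        records, regression_reps=config.regression_reps, seed=s_summ
    )

    result = PipelineResult(
        records=records,
        report=report,
        fits=records_to_frame(records),
        condition_summaries=summaries,
        additivity=add,
        additivity_frame=additivity_frame,
        regressions=regressions,
        age_trends=age_trends,
        trials=trials,
        truth=truth_frame,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result


def records_from_frame(fits: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild ParticipantRecords from a fits.csv-style table (inverse of
    :func:`sizebias.qc.records_to_frame`, for the staged CLI)."""
    records = []
    for pid, g in fits.groupby("participant_id", sort=True):
        fit_map = {}
        for _, row in g.iterrows():
            fit_map[row["condition"]] = qc.PsychometricFit(
                participant_id=pid,
                condition=row["condition"],
                mu_hat=row["mu_hat"],
                sigma_hat=row["sigma_hat"],
                mu_ci=(row["mu_ci_lo"], row["mu_ci_hi"]),
                sigma_ci=(row["sigma_ci_lo"], row["sigma_ci_hi"]),
                n_trials=int(row["n_trials"]),
                converged=bool(row["converged"]),
                log_likelihood=row["log_likelihood"],
            )
        first = g.iloc[0]
        records.append(
            ParticipantRecord(
                participant_id=pid,
                fits=fit_map,
                pooled_weber=first["pooled_weber"],
                group=first.get("group", "volunteer"),
                age=first.get("age", float("nan")),
                excluded=bool(first["excluded"]) if "excluded" in g.columns else False,
                exclusion_reasons=(
                    [r for r in str(first["exclusion_reasons"]).split(";") if r and r != "nan"]
                    if "exclusion_reasons" in g.columns
                    else []
                ),
                sign_corrected="sign_corrected" in g.columns and bool(first["sign_corrected"]),
            )
        )
    return records
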