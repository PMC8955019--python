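"""Group statistics: Wilcoxon vs enumeration, Deming regression vs brute
force, correlations, additivity and the age trend."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizebias import (
    OrthogonalRegression,
    PsychometricFit,
    compute_additivity,
    condition_summary,
    participant_weight,
    pearson_correlation,
    precision_age_trend,
    weighted_orthogonal_regression,
    wilcoxon_signed_rank,
)
from sizebias.qc import ParticipantRecord


def wilcoxon_enumeration_oracle(values):
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    ranks of |values| (no zeros, no ties)."""
    v = np.asarray(values, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(v))) + 1.0
    w_obs = ranks[v > 0].sum()
    n = len(v)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.array(dist)
    p_lo = np.mean(dist <= w_obs)
    p_hi = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        _, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(0.03125)

    def test_balanced_signs_near_one(self):
        _, p = wilcoxon_signed_rank([-1.0, 1.1, -2.0, 2.1, -3.0, 3.1])
        assert p > 0.8

    def test_zeros_dropped(self):
        s1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5])
        s2 = wilcoxon_signed_rank([1.0, 2.0, -0.5])
        assert s1 == s2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_center_shifts_null(self):
        _, p = wilcoxon_signed_rank([4.9, 5.1, 5.0 + 0.05, 4.93, 5.2, 4.85], null_center=5.0)
        assert p > 0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10).filter(lambda v: abs(v) > 1e-3),
            min_size=3,
            max_size=10,
            unique_by=lambda v: round(abs(v), 6),
        )
    )
    def test_matches_enumeration_for_small_n(self, values):
        _, p = wilcoxon_signed_rank(values)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(values), abs=1e-10)

    def test_large_shifted_sample_significant(self, rng):
        values = rng.normal(-4.7, 2.0, size=63)
        _, p = wilcoxon_signed_rank(values)
        assert p < 0.001


class TestParticipantWeight:
    def test_three_four_five(self):
        assert participant_weight((0.0, 3.0), (0.0, 4.0)) == pytest.approx(0.2)

    def test_unit_lengths(self):
        assert participant_weight((0.0, 1.0), (0.0, 1.0)) == pytest.approx(1 / np.sqrt(2))

    def test_homogeneity(self):
        w1 = participant_weight((0.0, 2.0), (0.0, 5.0))
        w2 = participant_weight((0.0, 4.0), (0.0, 10.0))
        assert w2 == pytest.approx(w1 / 2)

    def test_zero_length_capped(self):
        w = participant_weight((1.0, 1.0), (2.0, 2.0))
        assert np.isfinite(w) and w > 0

    def test_accepts_fit_objects(self):
        fit = PsychometricFit("p", "Balls", 0, 3, (0.0, 3.0), (2, 4), 90, True, -1.0)
        assert participant_weight(fit, (0.0, 4.0)) == pytest.approx(0.2)


def deming_closed_form(x, y):
    """Unweighted lambda=1 Deming slope (independent closed form)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


class TestOrthogonalRegression:
    def test_identity_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = weighted_orthogonal_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_swap_inverts_slope(self, rng):
        x = rng.normal(0, 3, 25)
        y = 0.6 * x + rng.normal(0, 1, 25)
        s_xy = weighted_orthogonal_regression(x, y).slope
        s_yx = weighted_orthogonal_regression(y, x).slope
        assert s_yx == pytest.approx(1 / s_xy, rel=1e-10)

    def test_equal_weights_match_closed_form(self, rng):
        x = rng.normal(-3, 2, 40)
        y = 1.2 * x + rng.normal(0, 1.5, 40)
        res = weighted_orthogonal_regression(x, y)
        assert res.slope == pytest.approx(deming_closed_form(x, y), abs=1e-10)

    def test_beats_random_probes(self, rng):
        x = rng.normal(0, 2, 20)
        y = -0.8 * x + 1 + rng.normal(0, 1, 20)
        w = rng.uniform(0.2, 2.0, 20)
        model = OrthogonalRegression(x, y, w)
        res = model.fit()
        best = model.objective(res.slope, res.intercept)
        slopes = np.tan(rng.uniform(-np.pi / 2 + 0.01, np.pi / 2 - 0.01, 10_000))
        intercepts = rng.uniform(-5, 5, 10_000)
        for s, a in zip(slopes, intercepts):
            assert best <= model.objective(s, a) + 1e-12

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError):
            weighted_orthogonal_regression([1.0] * 5, [2.0] * 5)

    def test_bootstrap_collinear_ci_collapses(self):
        x = np.linspace(0, 10, 12)
        res = weighted_orthogonal_regression(x, 2 * x + 1)
        lo, hi = res.bootstrap_slope_ci(reps=200, seed=3)
        assert lo == pytest.approx(2.0, abs=1e-9)
        assert hi == pytest.approx(2.0, abs=1e-9)

    def test_bootstrap_seeded(self, rng):
        x = rng.normal(0, 2, 15)
        y = x + rng.normal(0, 0.5, 15)
        a = weighted_orthogonal_regression(x, y).bootstrap_slope_ci(reps=200, seed=11)
        b = weighted_orthogonal_regression(x, y).bootstrap_slope_ci(reps=200, seed=11)
        assert a == b


class TestPearson:
    def test_collinear_is_one(self):
        assert pearson_correlation([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# cohort-level helpers on hand-built records
# ---------------------------------------------------------------------------

def _record(pid, biases, sigma=3.0, group="volunteer", age=25.0, excluded=False):
    fits = {
        c: PsychometricFit(pid, c, mu, sigma, (mu - 1, mu + 1), (sigma - 1, sigma + 1), 90, True, -20.0)
        for c, mu in biases.items()
    }
    rec = ParticipantRecord(pid, fits, pooled_weber=sigma, group=group, age=age)
    rec.excluded = excluded
    return rec


class TestConditionSummaryAndAdditivity:
    def test_single_participant_median(self):
        recs = [_record("a", {"Balls": 3.0, "Coins": 0.1, "Soccer": 1.0, "Tennis": 1.0})]
        assert condition_summary(recs, "Balls").median_bias == 3.0

    def test_median_of_symmetric_cohort_is_zero(self):
        recs = [
            _record(p, {"Balls": b, "Coins": 1.0, "Soccer": 1.0, "Tennis": 1.0})
            for p, b in (("a", -1.0), ("b", 0.5), ("c", 1.0))
        ]
        assert condition_summary(recs, "Balls").median_bias == 0.5
        assert condition_summary(recs, "Balls").n == 3

    def test_excluded_participants_ignored(self):
        recs = [
            _record("a", {"Balls": 1.0, "Coins": 0, "Soccer": 0, "Tennis": 0}),
            _record("bad", {"Balls": 99.0, "Coins": 0, "Soccer": 0, "Tennis": 0}, excluded=True),
        ]
        assert condition_summary(recs, "Balls").median_bias == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            condition_summary([], "Balls")

    def test_indirect_is_soccer_minus_tennis(self):
        recs = [_record("a", {"Balls": -4.0, "Coins": 0.0, "Soccer": -5.8, "Tennis": -1.5})]
        add = compute_additivity(recs)
        assert add.indirect[0] == pytest.approx(-4.3)

    def test_exactly_additive_cohort(self, rng):
        recs = []
        for i in range(15):
            s, t = rng.normal(-5, 2), rng.normal(1.5, 2)
            recs.append(_record(f"p{i}", {"Balls": s - t, "Coins": 0.0, "Soccer": s, "Tennis": t}))
        add = compute_additivity(recs)
        assert np.median(add.direct - add.indirect) == pytest.approx(0.0, abs=1e-12)
        assert add.paired_p == 1.0

    def test_soccer_equals_tennis_gives_zero_indirect(self):
        recs = [
            _record(f"p{i}", {"Balls": -1.0, "Coins": 0.0, "Soccer": 2.0, "Tennis": 2.0})
            for i in range(4)
        ]
        assert np.all(compute_additivity(recs).indirect == 0.0)

    def test_missing_condition_drops_participant(self):
        good = _record("a", {"Balls": -4.0, "Coins": 0.0, "Soccer": -5.0, "Tennis": -1.0})
        partial = _record("b", {"Coins": 0.0, "Soccer": -5.0, "Tennis": -1.0})
        add = compute_additivity([good, partial])
        assert add.participant_ids == ["a"]


class TestAgeTrend:
    def test_recovers_planted_slope(self, rng):
        slope = -0.05
        recs = []
        for i in range(200):
            age = rng.uniform(17, 73)
            sigma = 5.0 + slope * age + rng.normal(0, 0.3)
            recs.append(
                _record(f"p{i}", {c: 0.0 for c in ("Balls", "Coins", "Soccer", "Tennis")},
                        sigma=max(sigma, 0.3), age=age)
            )
        trend = precision_age_trend(recs, "volunteer")
        assert abs(trend.slope - slope) < trend.slope_ci_halfwidth

    def test_shuffled_ages_mostly_cover_zero(self, rng):
        ages = rng.uniform(17, 73, 40)
        sigmas = rng.uniform(2, 5, 40)
        covered = 0
        for _ in range(100):
            perm = rng.permutation(40)
            recs = [
                _record(f"p{i}", {c: 0.0 for c in ("Balls", "Coins", "Soccer", "Tennis")},
                        sigma=sigmas[i], age=ages[perm[i]])
                for i in range(40)
            ]
            trend = precision_age_trend(recs, "volunteer")
            covered += abs(trend.slope) <= trend.slope_ci_halfwidth
        assert covered >= 90

    def test_two_points_flagged(self):
        recs = [
            _record("a", {c: 0.0 for c in ("Balls", "Coins", "Soccer", "Tennis")}, age=20),
            _record("b", {c: 0.0 for c in ("Balls", "Coins", "Soccer", "Tennis")}, age=60),
        ]
        trend = precision_age_trend(recs, "volunteer")
        assert np.isnan(trend.slope_ci_halfwidth)
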