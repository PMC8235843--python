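"""Product-limit estimation, log-rank testing, Cox fitting and the
bootstrap optimism correction, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ctdna_kinetics.survival import (
    SurvivalRecord,
    bootstrap_optimism,
    km_estimate,
    logrank_test,
    median_split,
    ph_fit,
)
from ctdna_kinetics.variants import ValidationError


def records(times, events, groups=None):
    groups = groups or [None] * len(times)
    return [
        SurvivalRecord(
            patient_id=f"P{i}", time=t, event=bool(e),
            groups={} if g is None else {"group": g},
        )
        for i, (t, e, g) in enumerate(zip(times, events, groups))
    ]


def km_oracle(times, events):
    """Direct product-limit computation, ties events-before-censoring."""
    survival = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = sum(1 for x in times if x >= t)
        deaths = sum(1 for x, e in zip(times, events) if x == t and e)
        if at_risk:
            s *= 1.0 - deaths / at_risk
        survival[t] = s
    return survival


def logrank_oracle(times, events, groups):
    """Two-group log-rank by direct summation over the risk sets."""
    label = sorted(set(groups))[0]
    observed = expected = variance = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        n = sum(1 for x in times if x >= t)
        n1 = sum(1 for x, g in zip(times, groups) if x >= t and g == label)
        d = sum(1 for x, e in zip(times, events) if x == t and e)
        d1 = sum(
            1 for x, e, g in zip(times, events, groups)
            if x == t and e and g == label
        )
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return None
    return (observed - expected) ** 2 / variance


class TestKaplanMeier:
    def test_five_record_instance_matches_hand_computation(self):
        curve = km_estimate(records([1, 2, 3, 4, 5], [1, 0, 1, 1, 0]))
        by_time = dict(zip(curve.event_times, curve.survival))
        assert by_time[1] == pytest.approx(0.8)
        assert by_time[3] == pytest.approx(0.8 * (2 / 3))
        assert by_time[4] == pytest.approx(0.8 * (2 / 3) * 0.5)
        assert curve.median_time == 4

    def test_no_censoring_equals_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        curve = km_estimate(records(times, [1] * len(times)))
        n = len(times)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(sum(1 for x in times if x > t) / n)
        assert curve.median_time == np.median(times) or (
            # even n: product-limit median is the earliest time with S <= 0.5
            curve.median_time == sorted(times)[n // 2 - 1]
        )

    def test_all_censored_flat_at_one_median_undefined(self):
        curve = km_estimate(records([2, 4, 6], [0, 0, 0]))
        assert np.all(curve.survival == 1.0)
        assert curve.median_time is None

    def test_curve_is_non_increasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 15))
            times = rng.integers(1, 8, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            curve = km_estimate(records(times, events))
            assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            times = rng.integers(1, 6, size=n).astype(float)  # force ties
            events = rng.integers(0, 2, size=n)
            curve = km_estimate(records(times, events))
            oracle = km_oracle(list(times), list(events))
            for t, s in zip(curve.event_times, curve.survival):
                assert s == pytest.approx(oracle[t], abs=1e-10)

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValidationError):
            records([0.0], [1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 0]
        recs = records(times + times, events + events, ["a"] * 5 + ["b"] * 5)
        result = logrank_test(recs)
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert result.degrees_of_freedom == 1

    def test_swapping_group_labels_leaves_statistic_unchanged(self):
        times = [1, 3, 5, 2, 4, 8, 9]
        events = [1, 1, 0, 1, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        swapped = ["b" if g == "a" else "a" for g in groups]
        first = logrank_test(records(times, events, groups))
        second = logrank_test(records(times, events, swapped))
        assert first.chi_square == pytest.approx(second.chi_square, abs=1e-12)

    def test_uniform_time_rescaling_leaves_statistic_unchanged(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 8.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        first = logrank_test(records(times, events, groups))
        scaled = logrank_test(records([7.3 * t for t in times], events, groups))
        assert first.chi_square == pytest.approx(scaled.chi_square, rel=1e-12)

    def test_random_small_instances_match_direct_summation(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 9))
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            groups = [str(g) for g in rng.integers(0, 2, size=n)]
            if len(set(groups)) < 2:
                continue
            oracle = logrank_oracle(list(times), list(events), groups)
            if oracle is None:
                continue
            result = logrank_test(records(times, events, groups))
            assert result.chi_square == pytest.approx(oracle, abs=1e-10)
            checked += 1

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(records([1, 2], [1, 1], ["a", "a"]))


def exponential_two_group(n, rate_ratio, seed, censor_scale=50.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    raw = rng.exponential(1.0 / np.where(x == 1, rate_ratio, 1.0))
    censor = rng.exponential(censor_scale, size=n)
    return pd.DataFrame(
        {
            "time": np.maximum(np.minimum(raw, censor), 1e-6),
            "event": (raw <= censor).astype(int),
            "x": x,
        }
    )


class TestPhFit:
    def test_recovers_known_rate_ratio(self):
        frame = exponential_two_group(n=600, rate_ratio=3.0, seed=1)
        fit = ph_fit(frame, ["x"])
        cov = fit.covariates[0]
        assert fit.converged
        assert abs(cov.coefficient - np.log(3.0)) < 3 * cov.se
        assert cov.ci_low <= cov.hazard_ratio <= cov.ci_high
        assert cov.hazard_ratio == pytest.approx(np.exp(cov.coefficient))

    def test_sign_flip_of_covariate_negates_coefficient(self):
        frame = exponential_two_group(n=200, rate_ratio=2.5, seed=2)
        flipped = frame.assign(x=1 - frame["x"])
        a = ph_fit(frame, ["x"]).covariates[0]
        b = ph_fit(flipped, ["x"]).covariates[0]
        assert a.coefficient == pytest.approx(-b.coefficient, rel=1e-6)

    def test_constant_covariate_rejected(self):
        frame = exponential_two_group(n=50, rate_ratio=2.0, seed=3)
        frame["x"] = 1
        with pytest.raises(ValidationError, match="constant"):
            ph_fit(frame, ["x"])

    def test_fewer_than_two_events_rejected(self):
        frame = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [1, 0, 0], "x": [0, 1, 0]}
        )
        with pytest.raises(ValidationError):
            ph_fit(frame, ["x"])

    def test_separation_is_flagged_not_fatal(self):
        # events perfectly ordered by covariate -> monotone likelihood
        frame = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [1, 1, 1, 0, 0, 0],
            }
        )
        fit = ph_fit(frame, ["x"])
        assert not fit.converged


class _IdentityRng:
    """Degenerate RNG whose bootstrap resample is the original sample."""

    def integers(self, low, high, size):
        return np.arange(size)


class TestBootstrapOptimism:
    def test_degenerate_resample_gives_zero_optimism(self, monkeypatch):
        frame = exponential_two_group(n=80, rate_ratio=3.0, seed=4)
        monkeypatch.setattr(
            np.random, "default_rng", lambda seed=None: _IdentityRng()
        )
        result = bootstrap_optimism(frame, ["x"], B=1, seed=0)
        assert result.optimism == pytest.approx(0.0, abs=1e-12)
        assert result.corrected_concordance == pytest.approx(
            result.apparent_concordance
        )

    def test_fixed_seed_is_bit_identical(self):
        frame = exponential_two_group(n=60, rate_ratio=2.0, seed=5)
        a = bootstrap_optimism(frame, ["x"], B=25, seed=9)
        b = bootstrap_optimism(frame, ["x"], B=25, seed=9)
        assert a.optimism == b.optimism
        assert a.corrected_concordance == b.corrected_concordance
        assert a.b_used == b.b_used

    def test_somers_d_relation(self):
        frame = exponential_two_group(n=60, rate_ratio=2.0, seed=6)
        result = bootstrap_optimism(frame, ["x"], B=10, seed=2)
        assert result.corrected_somers_d == pytest.approx(
            2 * result.corrected_concordance - 1
        )

    def test_b_zero_rejected(self):
        frame = exponential_two_group(n=60, rate_ratio=2.0, seed=7)
        with pytest.raises(ValidationError):
            bootstrap_optimism(frame, ["x"], B=0, seed=0)


class TestMedianSplit:
    def test_values_at_median_go_high(self):
        assert median_split([1.0, 2.0, 3.0]) == ["low", "high", "high"]

    def test_two_groups_for_distinct_values(self):
        labels = median_split([0.1, 5.0, 9.9, 3.2])
        assert set(labels) == {"low", "high"}
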