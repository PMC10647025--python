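"""Threshold classifiers: exact fitting, window search, task semantics."""

import dataclasses
import math

import numpy as np
import pytest

from ribecho.errors import ConfigurationError, FittingError
from ribecho.preprocess import AlignedTrace, rectified_aligned
from ribecho.sim import CohortConfig, synth_dataset, synth_trace
from ribecho.thresholds import (NO_RIB, PARTIAL_RIB, RIB, WHOLE_RIB,
                                FreqThresholdModel, TimeThresholdModel,
                                classify_statistic, decision_statistic_freq,
                                decision_statistic_time, fit_freq_model,
                                fit_threshold, fit_time_model,
                                fit_time_window, predict_time, select_cohort,
                                trace_label)
from tests.conftest import make_participant
from tests.oracles import brute_force_threshold

FS = 2.5e7


def _aligned(v):
    return AlignedTrace(np.asarray(v, dtype=float), FS, "known")


class TestTaskMapping:
    def test_task1_drops_partial_locations(self):
        assert trace_label("B", 1) is None
        assert trace_label("A", 1) == NO_RIB
        assert trace_label("E", 1) == WHOLE_RIB

    def test_task2_pools_rib_classes(self):
        assert {trace_label(l, 2) for l in "BCDE"} == {RIB}

    def test_task3_is_ternary(self):
        assert trace_label("B", 3) == PARTIAL_RIB
        assert trace_label("C", 3) == WHOLE_RIB


class TestDecisionStatistic:
    def test_windowed_max(self):
        tr = _aligned([0.1, 4.0, 0.2, 9.0])
        assert decision_statistic_time(tr, (0, 3 / FS)) == 4.0

    def test_zero_segment(self):
        assert decision_statistic_time(_aligned(np.zeros(100)),
                                       (0, 100 / FS)) == 0.0

    def test_noiseless_statistic_equals_echo_peak(self, noiseless_config,
                                                  device):
        p = make_participant(rib_depth=2.0)
        tr = synth_trace(p, "C", device, noiseless_config, noise_seed=1)
        rect = rectified_aligned(tr, use_known_t0=True)
        s = decision_statistic_time(rect, (1.5e-5, 1.07e-4))
        from ribecho.sim import echo_peak_amplitude
        expected = echo_peak_amplitude(2.0, device,
                                       noiseless_config.attenuation_db_per_cm)
        assert s == pytest.approx(expected, rel=0.01)


class TestFitThreshold:
    def test_separated_classes(self):
        theta, err = fit_threshold([1, 2, 5, 6], [False, False, True, True])
        assert 2 < theta < 5
        assert err == 0.0

    def test_interleaved_classes(self):
        theta, err = fit_threshold([1, 3, 2, 4],
                                   [False, False, True, True])
        assert err == pytest.approx(0.25)

    def test_inseparable_constant(self):
        theta, err = fit_threshold([2.0, 2.0], [False, True])
        assert err == pytest.approx(0.5)
        assert theta == pytest.approx(1.0)  # below-min candidate, tie-break

    def test_single_class_rejected(self):
        with pytest.raises(FittingError):
            fit_threshold([1, 2, 3], [True, True, True])

    def test_matches_brute_force_oracle(self, rng):
        """Seeded fuzz: exact agreement with naive exhaustive search."""
        for _ in range(300):
            n = int(rng.integers(4, 60))
            stats = np.round(rng.normal(size=n) * rng.uniform(0.5, 5), 3)
            pos = rng.uniform(size=n) < 0.5
            if pos.all() or (~pos).all():
                continue
            theta, err = fit_threshold(stats, pos)
            o_theta, o_err = brute_force_threshold(stats, pos)
            assert err == pytest.approx(o_err, abs=1e-12)
            assert theta == pytest.approx(o_theta, abs=1e-12)

    def test_min_theta_constraint(self):
        theta, _ = fit_threshold([1, 2, 5, 6], [False, False, True, True],
                                 min_theta=4.0)
        assert theta > 4.0
        with pytest.raises(FittingError):
            fit_threshold([1, 2, 5, 6], [False, False, True, True],
                          min_theta=100.0)


class TestClassifyRules:
    def test_binary_boundary_is_positive(self):
        m = TimeThresholdModel(1, "all", 1.5e-5, 9e-5, theta1=2.8)
        assert classify_statistic(m, 2.8) == WHOLE_RIB
        assert classify_statistic(m, 0.0) == NO_RIB

    def test_ternary_interval_rule(self):
        m = TimeThresholdModel(3, "all", 1.5e-5, 9e-5, theta1=1.0, theta2=3.0)
        assert classify_statistic(m, 0.5) == NO_RIB
        assert classify_statistic(m, 2.0) == PARTIAL_RIB
        assert classify_statistic(m, 3.0) == WHOLE_RIB

    def test_monotone_in_statistic(self):
        """Raising the statistic never moves the label toward No Rib."""
        m = TimeThresholdModel(3, "all", 1.5e-5, 9e-5, theta1=1.0, theta2=3.0)
        order = {NO_RIB: 0, PARTIAL_RIB: 1, WHOLE_RIB: 2}
        labels = [order[classify_statistic(m, s)]
                  for s in np.linspace(0, 5, 101)]
        assert np.all(np.diff(labels) >= 0)

    def test_theta2_must_exceed_theta1(self):
        with pytest.raises(ConfigurationError):
            TimeThresholdModel(3, "all", 1.5e-5, 9e-5, theta1=3.0, theta2=2.0)


def _echo_cohort(depths, locations="AC", reps=2, noise_sd=0.02, seed=0):
    """Tiny cohort of hand-placed rib depths; returns (dataset-like lists)."""
    cc = dataclasses.replace(CohortConfig(), noise_sd=noise_sd)
    from ribecho.sim import Dataset, DeviceConfig
    parts = [make_participant(rib_depth=d, pid=f"P{i:02d}", bmi=24.0)
             for i, d in enumerate(depths)]
    traces = []
    s = seed
    for p in parts:
        for loc in locations:
            for r in range(reps):
                s += 1
                traces.append(synth_trace(p, loc, DeviceConfig(), cc,
                                          noise_seed=s, rep=r))
    return Dataset(parts, traces, DeviceConfig(), cc)


class TestWindowFitting:
    def test_zero_rounds_returns_init(self):
        rect = [_aligned(np.abs(np.random.default_rng(1).normal(size=1000)))
                for _ in range(4)]
        w = fit_time_window(rect, [True, True, False, False],
                            init_window=(2e-5, 3e-5), rounds=0)
        assert w == (2e-5, 3e-5)

    def test_recovers_echo_interval(self):
        """Echoes spanning 20-45 us pull the fitted window over them."""
        ds = _echo_cohort(depths=[1.48, 2.2, 3.0, 3.33], reps=3)
        rect = [rectified_aligned(t, use_known_t0=True) for t in ds.traces]
        pos = [t.location == "C" for t in ds.traces]
        start, end = fit_time_window(rect, pos)
        # excludes the artifact, overlaps the first (20 us) and last (45 us)
        # echo bursts (half-width 2.1 us)
        assert start >= 1.5e-5 - 1e-9
        assert start <= 22e-6
        assert end >= 43e-6

    def test_duplication_invariance(self):
        ds = _echo_cohort(depths=[1.6, 2.5], reps=2)
        rect = [rectified_aligned(t, use_known_t0=True) for t in ds.traces]
        pos = [t.location == "C" for t in ds.traces]
        w1 = fit_time_window(rect, pos)
        w2 = fit_time_window(rect + rect, list(pos) + list(pos))
        assert w1 == w2


class TestModelFitting:
    def test_separable_cohort_perfect_training_accuracy(self):
        ds = _echo_cohort(depths=[1.6, 2.0, 2.6, 3.0], reps=3, noise_sd=0.02)
        model = fit_time_model(ds, 1, "all", use_known_t0=True)
        preds = [predict_time(model, t, use_known_t0=True) for t in ds.traces]
        truth = [trace_label(t.location, 1) for t in ds.traces]
        assert preds == truth

    def test_task3_second_threshold_above_first(self):
        ds = _echo_cohort(depths=[1.6, 2.0, 2.6, 3.0], locations="ABC",
                          reps=2)
        model = fit_time_model(ds, 3, "all", use_known_t0=True)
        assert model.theta2 > model.theta1

    def test_cohort_filter_changes_window(self):
        """Disjoint echo-delay ranges per cohort give different windows."""
        low = _echo_cohort(depths=[1.5, 1.7, 1.9], reps=2)
        high = _echo_cohort(depths=[4.2, 4.6, 5.0], reps=2, seed=50)
        for p in high.participants:
            object.__setattr__(p, "bmi", 34.0)
            object.__setattr__(p, "cohort", "high_bmi")
            object.__setattr__(p, "id", "H" + p.id)
        for t in high.traces:
            t.participant_id = "H" + t.participant_id
        from ribecho.sim import Dataset
        merged = Dataset(low.participants + high.participants,
                         low.traces + high.traces, low.device_config,
                         low.cohort_config)
        m_low = fit_time_model(merged, 1, "low_bmi", use_known_t0=True)
        m_high = fit_time_model(merged, 1, "high_bmi", use_known_t0=True)
        assert m_low.window_end_s < m_high.window_end_s

    def test_select_cohort_filters_by_bmi(self, small_dataset):
        low = select_cohort(small_dataset, "low_bmi")
        ids = {t.participant_id for t in low}
        assert all(small_dataset.participant(i).cohort == "low_bmi"
                   for i in ids)


class TestFrequencyModels:
    def test_band_limited_statistic_ignores_out_of_band_tone(self):
        ds = _echo_cohort(depths=[2.0], locations="C", reps=1,
                          noise_sd=0.0)
        tr = ds.traces[0]
        from ribecho.preprocess import align
        base = decision_statistic_freq(align(tr, use_known_t0=True))
        t = np.arange(tr.voltage.size) / FS
        tr.voltage = tr.voltage + 0.05 * np.sin(2 * math.pi * 2e5 * t)
        contaminated = decision_statistic_freq(align(tr, use_known_t0=True))
        # only residual spectral leakage of the finite window remains
        assert contaminated == pytest.approx(base, rel=0.005)

    def test_zero_band_energy_classifies_no_rib(self):
        m = FreqThresholdModel(2, "all", theta1=5.0)
        assert classify_statistic(m, 0.0) == NO_RIB

    def test_separable_cohort_perfect_training_accuracy(self):
        ds = _echo_cohort(depths=[1.6, 2.0, 2.6, 3.0], reps=3)
        model = fit_freq_model(ds, 1, "all", use_known_t0=True)
        from ribecho.thresholds import predict_freq
        preds = [predict_freq(model, t, use_known_t0=True)
                 for t in ds.traces]
        truth = [trace_label(t.location, 1) for t in ds.traces]
        assert preds == truth

    def test_task3_thresholds_ordered(self):
        ds = _echo_cohort(depths=[1.6, 2.0, 2.6, 3.0], locations="ABC",
                          reps=2)
        model = fit_freq_model(ds, 3, "all", use_known_t0=True)
        assert model.theta2 > model.theta1
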