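"""Trace segmentation, dwell times, rate fits and the critical force."""

import numpy as np
import pytest

from ssbwrap.kinetics import (
    ForceExtensionTrace,
    InsufficientDataError,
    KineticFit,
    NoCrossoverError,
    RateEstimate,
    SegmentationSettings,
    critical_force,
    dwell_times,
    fit_rate,
    segment_trace,
)
from ssbwrap.synth import BellMode, ConditionSpec, make_telegraph_trace


def _trace(ext, rate=1.0, force=5.0):
    ext = np.asarray(ext, dtype=float)
    return ForceExtensionTrace(
        time=np.arange(ext.size) / rate, extension=ext, force=force, sampling_rate=rate
    )


def _square_wave(period_samples, n, lo=600.0, hi=630.0):
    states = (np.arange(n) // (period_samples // 2)) % 2
    return lo + (hi - lo) * states, states


class TestSegmentation:
    def test_noiseless_square_wave_recovered_exactly(self):
        ext, states = _square_wave(20, 200)
        seg = segment_trace(_trace(ext), SegmentationSettings(filter_width_s=0.0))
        assert seg.transitions_detected
        np.testing.assert_array_equal(seg.states, states)

    def test_constant_trace_reports_no_transitions(self):
        seg = segment_trace(_trace(np.full(500, 600.0)))
        assert not seg.transitions_detected
        assert seg.states is None

    def test_unimodal_noise_reports_no_transitions(self):
        rng = np.random.default_rng(0)
        seg = segment_trace(_trace(600.0 + 5.0 * rng.standard_normal(5000)))
        assert not seg.transitions_detected

    def test_accuracy_on_noisy_telegraph_traces(self):
        # 30 nm level separation, 5 nm noise: labels match generator truth
        spec = ConditionSpec(
            label="x",
            salt_mM=50.0,
            modes=(BellMode(k_bind0=0.2, k_unbind0=0.2, dx_bind=0.0, dx_unbind=0.0),),
            weights=(1.0,),
            noise_sd_nm=5.0,
        )
        accs = []
        for i in range(10):
            trace, truth = make_telegraph_trace(spec, force=5.0, duration=200.0, seed=7 + i)
            trace.extension = 600.0 + 30.0 * truth + (
                trace.extension - 600.0 - spec.extension_jump(5.0) * truth
            )
            seg = segment_trace(trace)
            accs.append(np.mean(seg.states == truth))
        assert np.mean(accs) >= 0.99

    def test_idempotent_and_offset_invariant(self):
        ext, _ = _square_wave(20, 400)
        rng = np.random.default_rng(3)
        ext = ext + rng.normal(0, 2.0, ext.size)
        a = segment_trace(_trace(ext))
        b = segment_trace(_trace(ext))
        c = segment_trace(_trace(ext + 123.4))
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.states, c.states)


class TestDwellTimes:
    def test_hand_counted_example(self):
        ds = dwell_times(np.array([0, 0, 1, 1, 1, 0]), sampling_rate=1.0)
        # one interior unbound dwell of 3 s; censored bound dwells of 2 s, 1 s
        assert ds.unbound_dwells.tolist() == [3.0]
        assert not ds.unbound_censored[0]
        assert sorted(ds.bound_dwells.tolist()) == [1.0, 2.0]
        assert ds.bound_censored.all()

    def test_square_wave_interior_dwells(self):
        _, states = _square_wave(10, 100)
        ds = dwell_times(states, sampling_rate=1.0)
        interior = np.concatenate(
            [ds.bound_dwells[~ds.bound_censored], ds.unbound_dwells[~ds.unbound_censored]]
        )
        assert interior.size == 18  # nine per state
        assert np.allclose(interior, 5.0)
        assert (~ds.bound_censored).sum() == 9

    def test_no_transition_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            ds = dwell_times(np.zeros(10, dtype=int), 1.0)
        assert ds.bound_dwells.size == 0

    def test_mean_dwell_matches_exponential_truth(self):
        rng = np.random.default_rng(42)
        k = 1.0
        dwells = rng.exponential(1.0 / k, 500)
        mean = dwells.mean()
        se = dwells.std() / np.sqrt(dwells.size)
        assert abs(mean - 1.0) < 3 * se


class TestFitRate:
    def test_exact_value_on_equal_dwells(self):
        est = fit_rate(np.full(4, 2.0), min_events=4)
        assert est.rate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.5 / 2.0)
        assert est.n_events == 4

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(3)
        dwells = rng.exponential(1.0 / 2.0, 1000)
        est = fit_rate(dwells)
        assert abs(est.rate - 2.0) < 3 * est.se

    def test_censored_dwell_lowers_estimate(self):
        dwells = np.full(10, 1.0)
        base = fit_rate(dwells).rate
        with_censored = fit_rate(
            np.append(dwells, 5.0), np.append(np.zeros(10, bool), True)
        ).rate
        assert with_censored < base

    def test_too_few_events_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_rate(np.array([1.0, 2.0]))


def _fit(force, kb, ku, se_frac=1e-6):
    return KineticFit(
        force=force,
        k_bind_obs=RateEstimate(kb, se_frac * kb, 1000),
        k_unbind=RateEstimate(ku, se_frac * ku, 1000),
    )


class TestCriticalForce:
    def test_symmetric_crossing_solved_by_hand(self):
        # ln k_bind = -F, ln k_unbind = F - 2 -> F_c = 1 pN
        fits = [_fit(f, np.exp(-f), np.exp(f - 2.0)) for f in (0.5, 1.0, 1.5, 2.0)]
        cf = critical_force(fits)
        assert cf.f_c == pytest.approx(1.0, abs=1e-6)
        assert cf.slope_bind < 0 < cf.slope_unbind

    def test_ligand_doubling_shifts_crossover_by_ln2_over_slope_gap(self):
        forces = (0.5, 1.0, 1.5, 2.0)
        base = critical_force([_fit(f, np.exp(-f), np.exp(f - 2.0)) for f in forces])
        doubled = critical_force(
            [_fit(f, 2.0 * np.exp(-f), np.exp(f - 2.0)) for f in forces]
        )
        shift = np.log(2.0) / (base.slope_unbind - base.slope_bind)
        assert doubled.f_c - base.f_c == pytest.approx(shift, rel=1e-6)

    def test_parallel_lines_raise_no_crossover(self):
        fits = [_fit(f, np.exp(-f), 2.0 * np.exp(-f)) for f in (1.0, 2.0, 3.0)]
        with pytest.raises(NoCrossoverError):
            critical_force(fits)

    def test_extrapolated_crossover_flagged(self):
        fits = [_fit(f, np.exp(-f), np.exp(f - 20.0)) for f in (1.0, 2.0, 3.0)]
        with pytest.warns(UserWarning):
            cf = critical_force(fits)
        assert cf.extrapolated

    def test_order_invariance_of_pooled_rates(self):
        rng = np.random.default_rng(5)
        dwells = rng.exponential(1.0, 200)
        a = fit_rate(dwells).rate
        b = fit_rate(dwells[::-1]).rate
        assert a == pytest.approx(b)
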