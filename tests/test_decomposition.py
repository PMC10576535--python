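import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gortlai.decomposition import (
    GaussianComponent,
    em_decompose,
    estimate_initial_components,
    fit_metrics,
    polish_components,
    project_interval,
    reconstruct_waveform,
    refine_amplitudes,
)
from gortlai.waveform_prep import Waveform, remove_noise

from conftest import gaussian_sum_waveform


class TestProjectInterval:
    @pytest.mark.parametrize("x,a,b,expected", [(1, 2, 5, 2), (3, 2, 5, 3), (7, 2, 5, 5)])
    def test_examples(self, x, a, b, expected):
        assert project_interval(x, a, b) == expected

    def test_empty_interval_errors(self):
        with pytest.raises(ValueError):
            project_interval(1.0, 5.0, 2.0)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_always_inside(self, x, a, width):
        p = project_interval(x, a, a + width)
        assert a <= p <= a + width


def _local_maxima_scan(amps):
    """Independent oracle: exhaustive interior local-maximum scan."""
    padded = np.concatenate(([-1.0], amps, [-1.0]))
    return [
        i - 1
        for i in range(1, len(padded) - 1)
        if padded[i] > padded[i - 1] and padded[i] >= padded[i + 1] and padded[i] > 0
    ]


class TestInitialComponents:
    def test_two_triangular_peaks(self):
        amps = np.zeros(40)
        amps[8:13] = [4, 8, 10, 8, 4]  # peak height 10 at bin 10
        amps[24:29] = [2, 4, 6, 4, 2]  # peak height 6 at bin 26
        wave = Waveform(amps, 300.0 - 0.15 * np.arange(40))
        comps = estimate_initial_components(wave)
        oracle = _local_maxima_scan(amps)
        assert [c.center for c in comps] == oracle == [10, 26]
        assert [c.amplitude for c in comps] == [10, 6]

    def test_single_gaussian_width_recovered(self):
        wave = gaussian_sum_waveform([(8.0, 30.0, 4.0)], 61)
        comps = estimate_initial_components(wave)
        assert len(comps) == 1
        assert comps[0].center == 30
        assert comps[0].amplitude == pytest.approx(8.0, rel=1e-6)
        assert comps[0].sigma == pytest.approx(4.0, rel=0.15)

    def test_flat_zeros_empty(self):
        wave = Waveform(np.zeros(20), 300.0 - 0.15 * np.arange(20))
        assert estimate_initial_components(wave) == []

    def test_small_peaks_dropped(self):
        wave = gaussian_sum_waveform([(100.0, 20.0, 3.0), (1.0, 50.0, 3.0)], 70)
        comps = estimate_initial_components(wave, min_amplitude_frac=0.05)
        assert len(comps) == 1

    def test_edge_peak_detected(self):
        amps = np.zeros(20)
        amps[0] = 5.0
        amps[1] = 3.0
        wave = Waveform(amps, 300.0 - 0.15 * np.arange(20))
        comps = estimate_initial_components(wave)
        assert [c.center for c in comps] == [0]


class TestEMDecompose:
    def test_noiseless_single_gaussian_recovery(self):
        wave = gaussian_sum_waveform([(10.0, 50.0, 5.0)], 101)
        init = estimate_initial_components(wave)
        d = em_decompose(wave, init)
        (c,) = d.components
        assert c.amplitude == pytest.approx(10.0, rel=0.01)
        assert c.center == pytest.approx(50.0, rel=0.01)
        assert c.sigma == pytest.approx(5.0, rel=0.01)
        assert d.fit["r2"] > 0.999

    def test_two_gaussians_with_noise(self):
        rng = np.random.default_rng(7)
        truth = [(100.0, 30.0, 4.0), (50.0, 60.0, 5.0)]
        wave = gaussian_sum_waveform(truth, 101, noise_sd=0.5, sigmean=5.0, rng=rng)
        wave = remove_noise(wave, 5.0, k=0.35)  # cut 1.75 (3.5 noise sd) above floor
        init = estimate_initial_components(wave)
        d = em_decompose(wave, init)
        assert d.n_components == 2
        for comp, (a, c, s) in zip(d.components, truth):
            assert abs(comp.center - c) < 0.5
            assert comp.amplitude == pytest.approx(a, rel=0.05)

    def test_constrained_centers_in_box(self, rng):
        for _ in range(20):
            truth = [
                (rng.uniform(20, 100), rng.uniform(20, 40), rng.uniform(2, 5)),
                (rng.uniform(20, 100), rng.uniform(55, 80), rng.uniform(2, 5)),
            ]
            wave = gaussian_sum_waveform(truth, 120, noise_sd=2.0, rng=rng)
            wave = remove_noise(wave, 0.0)
            init = estimate_initial_components(wave)
            if not init:
                continue
            d = em_decompose(wave, init, constrained=True)
            boxes = list(zip(d.state.init_centers, d.state.init_widths))
            for comp in d.components:
                assert any(
                    mu0 - s0 - 1e-9 <= comp.center <= mu0 + s0 + 1e-9 for mu0, s0 in boxes
                )

    def test_unconstrained_loglik_monotone(self, rng):
        truth = [(80.0, 25.0, 3.0), (40.0, 45.0, 4.0), (90.0, 70.0, 2.5)]
        wave = gaussian_sum_waveform(truth, 100, noise_sd=1.0, rng=rng)
        wave = remove_noise(wave, 0.0)
        d = em_decompose(wave, estimate_initial_components(wave), constrained=False)
        trace = np.asarray(d.state.loglik_trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9 * np.abs(trace[:-1]))

    def test_energy_closure(self):
        truth = [(100.0, 30.0, 4.0), (60.0, 70.0, 5.0)]
        wave = gaussian_sum_waveform(truth, 120)
        d = em_decompose(wave, estimate_initial_components(wave))
        assert d.fit["r2"] > 0.99
        total_mass = sum(c.amplitude * c.sigma * math.sqrt(2 * math.pi) for c in d.components)
        assert total_mass == pytest.approx(wave.amplitudes.sum(), rel=0.02)

    def test_empty_init_errors(self):
        wave = gaussian_sum_waveform([(10.0, 10.0, 2.0)], 30)
        with pytest.raises(ValueError):
            em_decompose(wave, [])

    def test_collapsing_component_dropped(self):
        wave = gaussian_sum_waveform([(10.0, 20.0, 3.0)], 50)
        init = [
            GaussianComponent(amplitude=10.0, center=20.0, sigma=3.0),
            GaussianComponent(amplitude=1e-9, center=45.0, sigma=1.0),
        ]
        d = em_decompose(wave, init, constrained=False)
        assert d.n_components == 1
        assert d.state.dropped == [1]

    def test_sigma_floor(self):
        amps = np.zeros(20)
        amps[10] = 5.0  # single-bin spike: degenerate sigma
        wave = Waveform(amps, 300.0 - 0.15 * np.arange(20))
        init = [GaussianComponent(amplitude=5.0, center=10.0, sigma=1.0)]
        d = em_decompose(wave, init)
        assert d.components[0].sigma >= 0.25


class TestRefinement:
    def test_refine_amplitudes_noiseless_identity(self):
        wave = gaussian_sum_waveform([(10.0, 30.0, 4.0), (6.0, 70.0, 5.0)], 110)
        d = em_decompose(wave, estimate_initial_components(wave))
        d2 = refine_amplitudes(d, wave)
        for a, b in zip(d.components, d2.components):
            assert b.amplitude == pytest.approx(a.amplitude, rel=0.01)
        assert abs(sum(c.weight for c in d2.components) - 1.0) < 1e-9

    def test_refine_amplitudes_beats_em_under_noise(self):
        rng = np.random.default_rng(3)
        truth = [(100.0, 30.0, 4.0), (100.0, 65.0, 5.0)]
        em_err, ref_err = [], []
        for _ in range(20):
            wave = gaussian_sum_waveform(truth, 110, noise_sd=5.0, sigmean=20.0, rng=rng)
            den = remove_noise(wave, 20.0, k=0.5)
            d = em_decompose(den, estimate_initial_components(den))
            d2 = refine_amplitudes(d, den)
            for a, c, s in truth:
                em_err.append(abs(min(d.components, key=lambda x: abs(x.center - c)).amplitude - a))
                ref_err.append(abs(min(d2.components, key=lambda x: abs(x.center - c)).amplitude - a))
        assert np.mean(ref_err) <= np.mean(em_err)

    def test_polish_noiseless_exact(self):
        wave = gaussian_sum_waveform([(10.0, 30.0, 4.0), (6.0, 70.0, 5.0)], 110)
        d = em_decompose(wave, estimate_initial_components(wave))
        d2 = polish_components(d, wave)
        assert d2.components[0].amplitude == pytest.approx(10.0, rel=1e-6)
        assert d2.components[0].center == pytest.approx(30.0, abs=1e-6)
        assert d2.components[1].sigma == pytest.approx(5.0, rel=1e-6)

    def test_polish_respects_center_slack(self):
        rng = np.random.default_rng(5)
        wave = gaussian_sum_waveform(
            [(100.0, 30.0, 4.0), (100.0, 60.0, 4.0)], 100, noise_sd=5.0, rng=rng
        )
        den = remove_noise(wave, 0.0)
        d = em_decompose(den, estimate_initial_components(den))
        d2 = polish_components(d, den, center_slack=1.0)
        for before, after in zip(d.components, d2.components):
            assert abs(after.center - before.center) <= 1.0 + 1e-9


class TestReconstruct:
    def test_peak_value(self):
        from gortlai.decomposition import Decomposition

        d = Decomposition(components=[GaussianComponent(amplitude=7.0, center=5.0, sigma=2.0)])
        assert reconstruct_waveform(d, np.array([5.0]))[0] == pytest.approx(7.0)

    def test_far_tail_is_bias(self):
        from gortlai.decomposition import Decomposition

        d = Decomposition(
            components=[GaussianComponent(amplitude=7.0, center=5.0, sigma=2.0)], bias=0.3
        )
        assert reconstruct_waveform(d, np.array([100.0]))[0] == pytest.approx(0.3, abs=1e-9)

    def test_self_consistent_r2(self):
        wave = gaussian_sum_waveform([(10.0, 20.0, 3.0)], 50)
        d = em_decompose(wave, estimate_initial_components(wave))
        fitted = reconstruct_waveform(d, np.arange(50, dtype=float))
        assert fit_metrics(wave.amplitudes, fitted)["r2"] == pytest.approx(d.fit["r2"])


class TestFitMetrics:
    def test_perfect(self):
        m = fit_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert m["r2"] == 1.0 and m["rmse"] == 0.0

    def test_mean_predictor(self):
        obs = np.array([1.0, 2, 3])
        m = fit_metrics(obs, np.full(3, obs.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        m = fit_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["rmse"] == pytest.approx(1 / math.sqrt(3))
        assert m["mse"] == pytest.approx(1 / 3)

    def test_constant_observed_r2_missing(self):
        m = fit_metrics(np.array([2.0, 2, 2]), np.array([1.0, 2, 3]))
        assert m["r2"] is None
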