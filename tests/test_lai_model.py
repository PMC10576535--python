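import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gortlai.canopy_energy import compute_energy_partition
from gortlai.decomposition import Decomposition, GaussianComponent
from gortlai.lai_model import (
    GortParams,
    fcover_above,
    fit_ndvi_lai,
    gap_probability,
    lai_fixed_ratio_baseline,
    lai_profile,
    lai_total,
)
from gortlai.synthetic_scene import forward_energies

from conftest import gaussian_sum_waveform

P = GortParams()  # clumping 1.58, projection 0.5


class TestGortParams:
    def test_defaults(self):
        assert P.clumping == 1.58 and P.projection == 0.5
        assert P.k == pytest.approx(3.16)

    @pytest.mark.parametrize("kw", [{"clumping": 0.0}, {"projection": 0.0}, {"projection": 1.5}])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            GortParams(**kw)


class TestFcover:
    def test_no_ground_energy_limit(self):
        assert fcover_above(400.0, 1000.0, 0.0, 2.0) == pytest.approx(0.4)

    def test_symmetric_case(self):
        assert fcover_above(1000.0, 1000.0, 1000.0, 1.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert fcover_above(500.0, 1000.0, 250.0, 2.0) == pytest.approx(1 / 3)

    def test_no_canopy_convention(self):
        assert fcover_above(0.0, 0.0, 100.0, 2.0) == 0.0

    def test_gap_complements(self):
        for args, fc in [
            ((400.0, 1000.0, 0.0, 2.0), 0.4),
            ((1000.0, 1000.0, 1000.0, 1.0), 0.5),
            ((500.0, 1000.0, 250.0, 2.0), 1 / 3),
        ]:
            assert gap_probability(*args) == pytest.approx(1 - fc)

    @given(
        rv0=st.floats(1e-3, 1e6),
        frac=st.floats(0, 1),
        rg=st.floats(0, 1e6),
        ratio=st.floats(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_in_unit_interval(self, rv0, frac, rg, ratio):
        fc = fcover_above(frac * rv0, rv0, rg, ratio)
        assert 0.0 <= fc <= 1.0


class TestLaiTotal:
    def test_zero_canopy(self):
        assert lai_total(0.0, 100.0, 2.45, P) == 0.0

    def test_reference_energies(self):
        # energies 2166.21 / 130.32 with the area-mean ratio 2.45
        assert lai_total(2166.21, 130.32, 2.45, P) == pytest.approx(6.484780483669374)
        assert lai_total(2166.21, 130.32, 2.45, P) == pytest.approx(6.49, abs=0.01)

    def test_zero_denominator_flagged(self):
        assert math.isnan(lai_total(100.0, 0.0, 2.45, P))

    def test_large_ratio_limit(self):
        lais = [lai_total(1000.0, 100.0, r, P) for r in (1, 10, 1e3, 1e6)]
        assert all(a > b for a, b in zip(lais, lais[1:]))
        assert lais[-1] == pytest.approx(0.0, abs=1e-2)

    @given(
        rv0=st.floats(1e-3, 1e5),
        rg=st.floats(1e-3, 1e5),
        ratio=st.floats(1e-3, 50),
    )
    @settings(max_examples=300, deadline=None)
    def test_identity_with_log_transform(self, rv0, rg, ratio):
        from hypothesis import assume

        assume(ratio * rg / rv0 >= 1e-6)  # below saturation guard, 1 - fc is exact
        fc = fcover_above(rv0, rv0, rg, ratio)
        assert lai_total(rv0, rg, ratio, P) == pytest.approx(
            -P.k * math.log1p(-fc), rel=1e-9
        )

    @given(
        rv0=st.floats(1.0, 1e4),
        rg=st.floats(1.0, 1e4),
        ratio=st.floats(0.1, 10),
        factor=st.floats(1.1, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, rv0, rg, ratio, factor):
        base = lai_total(rv0, rg, ratio, P)
        assert lai_total(rv0 * factor, rg, ratio, P) > base
        assert lai_total(rv0, rg, ratio * factor, P) < base

    @given(lai=st.floats(0, 8), ratio=st.floats(0.2, 5), rg=st.floats(1, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_forward_inverse_round_trip(self, lai, ratio, rg):
        rv0 = forward_energies(lai, ratio, rg, P)
        assert lai_total(rv0, rg, ratio, P) == pytest.approx(lai, rel=1e-9, abs=1e-9)


class TestLaiProfile:
    def _partition(self):
        comps = [
            GaussianComponent(amplitude=10.0, center=40.0, sigma=4.0),
            GaussianComponent(amplitude=20.0, center=160.0, sigma=2.0),
        ]
        wave = gaussian_sum_waveform([(c.amplitude, c.center, c.sigma) for c in comps], 220)
        return compute_energy_partition(Decomposition(components=comps), wave)

    def test_zero_cover_zero_lai(self):
        part = self._partition()
        profile = lai_profile(part, 2.45, P)
        assert profile(part.cum_elevations[0]) == pytest.approx(0.0, abs=1e-12)

    def test_bottom_matches_total(self):
        part = self._partition()
        profile = lai_profile(part, 2.45, P)
        total = lai_total(part.rv0, part.rg, 2.45, P)
        assert profile(part.cum_elevations[-1]) == pytest.approx(total, rel=1e-9)

    def test_halving_cover_ratio(self):
        # -k*ln(0.2) / -k*ln(0.6) for covers 0.8 and 0.4
        assert (-P.k * math.log(0.2)) / (-P.k * math.log(0.6)) == pytest.approx(
            3.150660103087123
        )

    def test_saturation_flagged(self):
        part = self._partition()
        part.rg = 0.0  # cover -> 1 at the bottom
        profile = lai_profile(part, 2.45, P)
        with pytest.raises(ValueError, match="saturated"):
            profile(part.cum_elevations[-1])

    def test_non_decreasing_downward(self):
        part = self._partition()
        profile = lai_profile(part, 2.45, P)
        values = [profile(z) for z in part.cum_elevations[::20]]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestFixedBaseline:
    def test_reference_value(self):
        res = lai_fixed_ratio_baseline(2166.21, 130.32, P, ratio=2.5)
        assert res.lai == pytest.approx(6.429213381168909)
        assert res.lai == pytest.approx(6.43, abs=0.01)
        assert res.ratio_source == "fixed"

    def test_larger_ratio_smaller_lai(self):
        l25 = lai_fixed_ratio_baseline(2166.21, 130.32, P, ratio=2.5).lai
        l20 = lai_fixed_ratio_baseline(2166.21, 130.32, P, ratio=2.0).lai
        assert l25 < l20

    def test_zero_canopy(self):
        assert lai_fixed_ratio_baseline(0.0, 100.0, P).lai == 0.0


class TestNdviLai:
    def test_two_point_exact_line(self):
        m = fit_ndvi_lai(np.array([0.2, 0.8]), np.array([1.0, 4.0]))
        assert m.slope == pytest.approx(5.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery(self):
        ndvi = np.linspace(0.1, 0.9, 20)
        m = fit_ndvi_lai(ndvi, 2.0 + 6.0 * ndvi)
        assert m.slope == pytest.approx(6.0) and m.intercept == pytest.approx(2.0)
        assert m.r2 == pytest.approx(1.0)

    def test_noisy_simulation(self):
        rng = np.random.default_rng(11)
        ndvi = rng.uniform(0.1, 0.9, 200)
        lai = 2.0 + 6.0 * ndvi + rng.normal(0, 0.3, 200)
        m = fit_ndvi_lai(ndvi, lai)
        assert m.slope == pytest.approx(6.0, rel=0.05)

    def test_prediction_floored_at_zero(self):
        m = fit_ndvi_lai(np.array([0.2, 0.8]), np.array([1.0, 4.0]))
        assert m.predict(np.array([-0.5]))[0] == 0.0

    def test_constant_ndvi_errors(self):
        with pytest.raises(ValueError, match="singular"):
            fit_ndvi_lai(np.full(5, 0.5), np.arange(5.0))
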