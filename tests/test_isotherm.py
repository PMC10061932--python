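"""Surface tension/pressure, APL, windowed isotherms and isotherm shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofilm.isotherm import (
    area_per_lipid,
    isotherm_shift,
    surface_pressure,
    surface_tension,
    windowed_isotherm,
)
from monofilm.synth import generate_pressure_series


class TestSurfaceTension:
    def test_isotropic_pressure_gives_zero(self):
        assert surface_tension(10.0, 10.0, 10.0, 20.0) == 0.0

    def test_hand_computed_value(self):
        # 0.1 * (20/2) * 72 = 72.0 mN/m
        assert surface_tension(-71.0, -73.0, 0.0, 20.0) == pytest.approx(72.0)

    @given(
        scale=st.floats(0.1, 10.0),
        aniso=st.floats(-100.0, 100.0),
        lz=st.floats(1.0, 50.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_linearity_in_anisotropy_and_lz(self, scale, aniso, lz):
        base = surface_tension(-aniso, -aniso, 0.0, lz)
        assert surface_tension(-scale * aniso, -scale * aniso, 0.0, lz) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-9
        )
        assert surface_tension(-aniso, -aniso, 0.0, 2 * lz) == pytest.approx(2 * base, rel=1e-12)


class TestSurfacePressureAndApl:
    def test_pi_arithmetic(self):
        assert surface_pressure(70.0, 70.0) == 0.0
        assert surface_pressure(20.0, 70.0) == 50.0
        assert surface_pressure(75.0, 70.0) == -5.0  # negative passes through

    def test_169_lipids_at_90_A2(self):
        # 152.1 nm^2 of interface and 169 lipids per leaflet -> 90 A^2
        edge = np.sqrt(152.1)
        assert area_per_lipid(edge, edge, 169) == pytest.approx(90.0)

    def test_protein_never_subtracted(self):
        # same box, same lipid count: APL is blind to any protein present
        assert area_per_lipid(10.0, 10.0, 100) == area_per_lipid(10.0, 10.0, 100) == 100.0


class TestWindowedIsotherm:
    def test_constant_series(self):
        t = np.linspace(0.0, 500.0, 1000, endpoint=False)
        iso = windowed_isotherm(t, np.full_like(t, 60.0), np.full_like(t, 30.0), window=100.0)
        assert len(iso) == 5
        assert np.allclose(iso["apl_mean"], 60.0)
        assert np.allclose(iso["pi_mean"], 30.0)
        assert np.allclose(iso["apl_sd"], 0.0)

    def test_linear_ramp_window_means_are_midpoints(self):
        t = np.arange(0.0, 300.0, 0.5)
        apl = 90.0 - 0.1 * t
        pi = 0.2 * t
        iso = windowed_isotherm(t, apl, pi, window=100.0)
        for _, row in iso.iterrows():
            sel = (t >= row.window_center_time - 50.0) & (t < row.window_center_time + 50.0)
            assert row.apl_mean == pytest.approx(apl[sel].mean(), abs=1e-12)
            assert row.pi_mean == pytest.approx(pi[sel].mean(), abs=1e-12)

    def test_record_count_and_partial_flag(self):
        t = np.arange(0.0, 250.0, 1.0)
        iso = windowed_isotherm(t, np.ones_like(t), np.ones_like(t), window=100.0)
        assert len(iso) == int(np.ceil((t[-1] - t[0]) / 100.0))
        assert bool(iso["partial"].iloc[-1])
        assert not iso["partial"].iloc[:-1].any()

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            windowed_isotherm(np.array([]), np.array([]), np.array([]))

    def test_noisy_plant_recovered_within_clt_bound(self):
        t = np.arange(0.0, 1000.0, 0.1)  # 1000 samples per 100 ns window
        # 2 mN/m of tension noise per sample (20 bar*nm of anisotropy),
        # expressed as independent noise on Pxx and Pyy
        gamma_noise, lz = 2.0, 15.0
        noise_sd = gamma_noise * np.sqrt(2.0) / (0.1 * lz / 2.0)
        series, truth = generate_pressure_series(
            t, lambda x: 70.0 - 0.05 * x, Lz=lz, noise_sd=noise_sd, seed=4
        )
        gamma = surface_tension(series.Pxx, series.Pyy, series.Pzz, series.Lz)
        iso = windowed_isotherm(series.time, series.apl, 70.0 - gamma, window=100.0)
        truth_iso = windowed_isotherm(truth.time, truth.APL, truth.pi_true, window=100.0)
        # window-mean noise is gamma_noise/sqrt(1000) ~ 0.063; 0.5 is ~8 sigma
        err = np.abs(iso["pi_mean"] - truth_iso["pi_mean"])
        assert err.max() < 0.5


class TestIsothermShift:
    @staticmethod
    def _iso(pi_offset=0.0, noise=None, seed=0):
        t = np.arange(0.0, 4500.0, 10.0)
        apl = np.linspace(90.0, 45.0, t.size)
        pi = np.clip(2.0 * (85.0 - apl), 0, None) + pi_offset
        if noise:
            pi = pi + np.random.default_rng(seed).normal(0.0, noise, t.size)
        return windowed_isotherm(t, apl, pi, window=100.0)

    def test_identical_isotherms_give_zero(self):
        iso = pd.DataFrame(
            {
                "apl_mean": np.linspace(45.0, 90.0, 20),
                "pi_mean": np.linspace(50.0, 0.0, 20),
                "pi_se": np.zeros(20),
            }
        )
        delta, se = isotherm_shift(iso, iso)
        assert delta == 0.0 and se == 0.0

    def test_constant_offset_recovered_exactly(self):
        delta, _ = isotherm_shift(self._iso(), self._iso(pi_offset=5.0))
        assert delta == pytest.approx(5.0, abs=1e-9)

    def test_antisymmetry(self):
        a, b = self._iso(noise=1.0, seed=1), self._iso(pi_offset=3.0, noise=1.0, seed=2)
        d_ab, _ = isotherm_shift(a, b)
        d_ba, _ = isotherm_shift(b, a)
        assert d_ab == pytest.approx(-d_ba, abs=1e-9)

    def test_planted_7p6_offset_within_3_se(self):
        # the per-window noise is 1 mN/m across ~45 windows, as in a long
        # compression run; the planted shift must come back within 3 SE
        rng_shift = 7.6
        deltas = []
        for seed in range(5):
            ref = self._iso(noise=1.0, seed=10 + seed)
            test = self._iso(pi_offset=rng_shift, noise=1.0, seed=100 + seed)
            delta, se = isotherm_shift(ref, test)
            assert se > 0
            assert abs(delta - rng_shift) < 3 * max(se, 1e-6)
            deltas.append(delta)
        assert np.mean(deltas) == pytest.approx(rng_shift, abs=0.5)

    def test_insufficient_overlap_is_error(self):
        t = np.arange(0.0, 400.0, 10.0)
        lo = windowed_isotherm(t, np.linspace(50, 55, t.size), np.ones(t.size), window=100.0)
        hi = windowed_isotherm(t, np.linspace(80, 85, t.size), np.ones(t.size), window=100.0)
        with pytest.raises(ValueError, match="overlap"):
            isotherm_shift(lo, hi)
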