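"""Generator contracts: seed determinism, planted bookkeeping, closed forms."""

import numpy as np
import pytest

from monofilm.synth import (
    BrownianSpec,
    GeometryError,
    MonolayerSpec,
    ProteinSpec,
    generate_brownian,
    generate_compression_stack,
    generate_monolayer,
    generate_pressure_series,
)
from monofilm.isotherm import surface_tension
from monofilm.pbc import pair_distance_matrix


class TestMonolayer:
    def test_seed_determinism(self):
        spec = MonolayerSpec(n_lipids_per_leaflet=60, f_lc=0.3, seed=9)
        _, f1, t1 = generate_monolayer(spec)
        _, f2, t2 = generate_monolayer(spec)
        assert np.array_equal(f1.positions, f2.positions)
        assert t1.markers.equals(t2.markers)
        _, f3, _ = generate_monolayer(MonolayerSpec(n_lipids_per_leaflet=60, f_lc=0.3, seed=10))
        assert not np.array_equal(f1.positions, f3.positions)

    def test_zero_condensed_fraction(self):
        _, _, truth = generate_monolayer(MonolayerSpec(n_lipids_per_leaflet=50, f_lc=0.0, seed=2))
        assert truth.lc_fraction() == 0.0

    def test_full_condensed_single_patch_is_exact_lattice(self):
        spec = MonolayerSpec(n_lipids_per_leaflet=60, f_lc=1.0, patch_count=1, apl=70.0, seed=4)
        top, frame, truth = generate_monolayer(spec)
        assert truth.lc_fraction() == 1.0
        markers = truth.markers[truth.markers.leaflet == "upper"][["x", "y"]].to_numpy()
        dist = pair_distance_matrix(markers, frame.box[:2])
        np.fill_diagonal(dist, np.inf)
        assert abs(dist.min() - spec.lattice_spacing) < 1e-9

    def test_planted_fraction_within_rounding(self):
        spec = MonolayerSpec(n_lipids_per_leaflet=400, f_lc=0.4, seed=7)
        _, _, truth = generate_monolayer(spec)
        # 2 chains per phospholipid + 1 per CHOL, per leaflet
        n_chains = 2 * 360 + 40
        assert abs(truth.lc_fraction() - round(0.4 * n_chains) / n_chains) < 1e-12

    def test_expanded_markers_respect_minimum_distance(self, small_monolayer):
        spec, _, frame, truth = small_monolayer
        le = truth.markers.query("leaflet == 'upper' and phase == 'Le'")[["x", "y"]].to_numpy()
        dist = pair_distance_matrix(le, frame.box[:2])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= spec.le_min_distance - 1e-9

    def test_full_halo_suppression_empties_the_halo(self, protein_monolayer):
        spec, topology, frame, truth = protein_monolayer
        from monofilm.phases import min_distance_to_set

        up = truth.markers[truth.markers.leaflet == "upper"]
        d = min_distance_to_set(
            up[["x", "y"]].to_numpy(), truth.protein_xy["upper"], frame.box[:2]
        )
        in_halo = d <= spec.protein.halo_width
        assert in_halo.sum() > 0
        assert (up["phase"].to_numpy()[in_halo] == "Lc").sum() == 0

    def test_infeasible_packing_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            generate_monolayer(MonolayerSpec(n_lipids_per_leaflet=100, apl=40.0, f_lc=0.0, seed=0))


class TestBrownian:
    def test_zero_diffusion_is_static(self):
        _, traj, unwrapped = generate_brownian(BrownianSpec(D_true=0.0, n_particles=5, n_steps=10))
        assert np.allclose(unwrapped[0], unwrapped[-1])
        assert np.allclose(traj.positions[0], traj.positions[-1])

    def test_step_variance_matches_2Ddt(self):
        spec = BrownianSpec(D_true=0.5, n_particles=1000, dt=0.1, n_steps=100, seed=3)
        _, _, unwrapped = generate_brownian(spec)
        steps = np.diff(unwrapped[:, :, :2], axis=0).ravel()
        # mean per-axis squared step = 2 D dt, n = 2e5 samples
        expected = 2 * spec.D_true * spec.dt
        se = expected * np.sqrt(2.0 / steps.size)
        assert abs(np.mean(steps**2) - expected) < 3 * se

    def test_seed_determinism(self):
        a = generate_brownian(BrownianSpec(seed=1))[2]
        b = generate_brownian(BrownianSpec(seed=1))[2]
        c = generate_brownian(BrownianSpec(seed=2))[2]
        assert np.array_equal(a, b) and not np.array_equal(a, c)


class TestPressureSeries:
    def test_noise_free_schedule_recovered_exactly(self):
        times = np.arange(0.0, 10.0, 0.1)
        series, truth = generate_pressure_series(times, 50.0, gamma0=70.0, noise_sd=0.0)
        gamma = surface_tension(series.Pxx, series.Pyy, series.Pzz, series.Lz)
        assert np.allclose(gamma, 50.0, atol=1e-12)
        assert np.allclose(truth["pi_true"], 20.0)

    def test_zero_surface_pressure_at_gamma0(self):
        times = np.linspace(0, 5, 20)
        series, truth = generate_pressure_series(times, 70.0, gamma0=70.0, noise_sd=0.0)
        gamma = surface_tension(series.Pxx, series.Pyy, series.Pzz, series.Lz)
        assert np.allclose(70.0 - gamma, 0.0, atol=1e-12)

    def test_apl_ramp_endpoints(self):
        times = np.linspace(0, 100, 11)
        series, _ = generate_pressure_series(times, 50.0, apl_range=(90.0, 45.0))
        assert series.apl[0] == pytest.approx(90.0)
        assert series.apl[-1] == pytest.approx(45.0)
        assert np.all(np.diff(series.apl) < 0)


class TestCompressionStack:
    def test_planted_fractions_and_monotonicity_guard(self):
        spec = MonolayerSpec(n_lipids_per_leaflet=100, seed=5)
        stack = generate_compression_stack(spec, [90.0, 70.0, 58.0], {90.0: 0.0, 70.0: 0.3, 58.0: 0.6})
        assert len(stack) == 3
        for (_, frame, truth), f in zip(stack, [0.0, 0.3, 0.6]):
            assert abs(truth.lc_fraction() - f) < 0.02  # rounding + parity only
        with pytest.raises(ValueError, match="nonincreasing"):
            generate_compression_stack(spec, [90.0, 55.0], {90.0: 0.5, 55.0: 0.1})

    def test_shared_topology_across_stack(self):
        spec = MonolayerSpec(n_lipids_per_leaflet=60, seed=5, protein=ProteinSpec(n_beads=20))
        stack = generate_compression_stack(spec, [90.0, 70.0], {90.0: 0.1, 70.0: 0.4})
        t0, t1 = stack[0][0], stack[1][0]
        assert np.array_equal(t0.resname, t1.resname)
        assert np.array_equal(t0.atom_name, t1.atom_name)
        assert np.array_equal(t0.mol_id, t1.mol_id)
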