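"""Periodic DBSCAN, condensed-phase labeling and protein-distance profiles."""

import numpy as np
import pytest
from reference_impl import dbscan_reference, partition_signature

import monofilm as mf
from monofilm.phases import (
    PeriodicDBSCAN,
    dbscan_pbc,
    lc_fraction,
    lc_fraction_vs_distance,
    phase_labels,
)
from monofilm.synth import MonolayerSpec, generate_monolayer


def hex_lattice(spacing, nx, ny):
    pts = []
    for j in range(ny):
        for i in range(nx):
            pts.append((i * spacing + (j % 2) * spacing / 2, j * spacing * np.sqrt(3) / 2))
    return np.asarray(pts) + 1.0


class TestDbscanPbc:
    def test_sparse_points_are_noise(self, rng):
        box = np.array([100.0, 100.0])
        pts = rng.uniform(5, 95, size=(10, 2))  # pairwise >> eps
        labels = dbscan_pbc(pts, box, eps=0.55, min_pts=4)
        assert np.all(labels == -1)

    def test_hexagonal_lattice_is_one_cluster(self):
        a = 0.48
        pts = hex_lattice(a, 6, 6)
        labels = dbscan_pbc(pts, np.array([50.0, 50.0]), eps=1.2 * a, min_pts=4)
        assert set(labels) == {0}

    def test_cluster_wraps_across_periodic_seam(self):
        # a lattice strip straddling x = 0 must cluster as one unit
        a = 0.48
        pts = hex_lattice(a, 6, 4)
        box = np.array([10.0, 10.0])
        shifted = np.mod(pts + [-2.0, 0.0], box)
        labels = dbscan_pbc(shifted, box, eps=1.2 * a, min_pts=4)
        assert set(labels) == {0}

    def test_eps_beyond_half_box_is_error(self):
        with pytest.raises(ValueError, match="minimum-image"):
            dbscan_pbc(np.zeros((5, 2)), np.array([1.0, 10.0]), eps=0.6, min_pts=2)

    def test_matches_brute_force_reference(self, rng):
        """Oracle equivalence on 50 random periodic instances."""
        box = np.array([10.0, 10.0])
        for seed in range(50):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, 10, size=(200, 2))
            ours = dbscan_pbc(pts, box, eps=0.55, min_pts=4)
            ref = dbscan_reference(pts, box, eps=0.55, min_pts=4)
            assert partition_signature(ours) == partition_signature(ref), f"seed {seed}"

    def test_matches_sklearn_core_points(self, rng):
        """Independent library cross-check on core samples and their partition."""
        from sklearn.cluster import DBSCAN

        from reference_impl import minimum_image_matrix

        box = np.array([8.0, 8.0])
        pts = rng.uniform(0, 8, size=(150, 2))
        est = PeriodicDBSCAN(eps=0.7, min_samples=4, box=box).fit(pts)
        sk = DBSCAN(eps=0.7, min_samples=4, metric="precomputed").fit(
            minimum_image_matrix(pts, box)
        )
        assert np.array_equal(est.core_sample_indices_, sk.core_sample_indices_)
        core = est.core_sample_indices_
        assert partition_signature(est.labels_[core]) == partition_signature(sk.labels_[core])

    def test_label_canonicalization_under_permutation(self, rng):
        box = np.array([10.0, 10.0])
        pts = rng.uniform(0, 10, size=(120, 2))
        labels = dbscan_pbc(pts, box, eps=0.8, min_pts=3)
        perm = rng.permutation(120)
        labels_perm = dbscan_pbc(pts[perm], box, eps=0.8, min_pts=3)
        assert partition_signature(labels) == partition_signature(
            np.asarray([labels_perm[np.flatnonzero(perm == i)[0]] for i in range(120)])
        )

    def test_sklearn_estimator_api(self):
        from sklearn.base import clone

        est = PeriodicDBSCAN(eps=0.5, min_samples=3, box=[5.0, 5.0])
        params = est.get_params()
        assert params["eps"] == 0.5
        cloned = clone(est)
        assert cloned.get_params() == params


class TestPhaseLabels:
    def test_planted_fraction_recovery(self, small_monolayer):
        _, topology, frame, truth = small_monolayer
        for leaflet in ("upper", "lower"):
            labeling = phase_labels(frame, topology, leaflet)
            assert abs(lc_fraction(labeling) - truth.lc_fraction(leaflet)) <= 0.03

    def test_f_lc_zero_gives_zero(self):
        topology, frame, _ = generate_monolayer(
            MonolayerSpec(n_lipids_per_leaflet=80, f_lc=0.0, seed=6)
        )
        assert lc_fraction(phase_labels(frame, topology, "upper")) == 0.0

    def test_min_cluster_size_larger_than_n_gives_zero(self, small_monolayer):
        _, topology, frame, _ = small_monolayer
        labeling = phase_labels(frame, topology, "upper", min_cluster_size=10_000)
        assert lc_fraction(labeling) == 0.0

    def test_lc_fraction_monotone_in_parameters(self, small_monolayer):
        _, topology, frame, _ = small_monolayer
        # nonincreasing in min_cluster_size
        fracs = [
            lc_fraction(phase_labels(frame, topology, "upper", min_cluster_size=m))
            for m in (5, 10, 40, 200)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        # nondecreasing in eps
        fracs_eps = [
            lc_fraction(phase_labels(frame, topology, "upper", eps=e))
            for e in (0.45, 0.55, 0.75)
        ]
        assert all(a <= b for a, b in zip(fracs_eps, fracs_eps[1:]))

    def test_every_marker_labeled(self, small_monolayer):
        _, topology, frame, _ = small_monolayer
        labeling = phase_labels(frame, topology, "upper")
        n_markers = (
            (topology.role_mask("chain_marker") | topology.role_mask("chol_marker"))
            & (topology.atom_leaflet() == "upper")
        ).sum()
        assert len(labeling) == n_markers
        assert set(labeling["phase"]) <= {"Lc", "Le"}


class TestLcVsDistance:
    def test_full_halo_profile(self, protein_monolayer):
        spec, topology, frame, truth = protein_monolayer
        labeling = phase_labels(frame, topology, "upper")
        prot_xy = frame.positions[topology.role_mask("protein"), :2]
        bins = np.arange(0.0, 5.01, 0.5)
        prof = lc_fraction_vs_distance(labeling, prot_xy, frame.box[:2], bins)
        near = prof[prof.bin_hi <= spec.protein.halo_width]
        assert (near["lc_fraction"].dropna() < 0.05).all()
        # beyond the halo the recovered profile tracks the planted one
        truth_prof = lc_fraction_vs_distance(
            labeling.assign(phase=_true_phase(labeling, truth, "upper")),
            prot_xy, frame.box[:2], bins,
        )
        far = prof[prof.bin_lo >= 2.5].dropna()
        far_truth = truth_prof[truth_prof.bin_lo >= 2.5].dropna()
        assert np.allclose(far["lc_fraction"], far_truth["lc_fraction"], atol=0.05)

    def test_uniform_labels_give_flat_profile(self, rng):
        n = 4000
        box = np.array([40.0, 40.0])
        xy = rng.uniform(0, 40, size=(n, 2))
        phase = np.where(rng.uniform(size=n) < 0.3, "Lc", "Le")
        import pandas as pd

        labeling = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "phase": phase})
        prof = lc_fraction_vs_distance(labeling, np.array([[20.0, 20.0]]), box, np.arange(0, 16, 2.0))
        filled = prof.dropna()
        # binomial 4-sigma envelope per bin
        p = 0.3
        for _, row in filled.iterrows():
            se = np.sqrt(p * (1 - p) / row.n_markers)
            assert abs(row.lc_fraction - p) < 4 * se + 1e-9

    def test_single_marker_bin(self):
        import pandas as pd

        labeling = pd.DataFrame({"x": [2.3], "y": [0.0], "phase": ["Lc"]})
        prof = lc_fraction_vs_distance(
            labeling, np.array([[0.0, 0.0]]), np.array([20.0, 20.0]), [0.0, 1.0, 2.0, 3.0]
        )
        assert prof.loc[2, "lc_fraction"] == 1.0
        assert np.isnan(prof.loc[0, "lc_fraction"])  # empty bin is missing, not 0

    def test_no_protein_is_error(self, small_monolayer):
        _, topology, frame, _ = small_monolayer
        labeling = phase_labels(frame, topology, "upper")
        with pytest.raises(ValueError, match="protein"):
            lc_fraction_vs_distance(labeling, np.empty((0, 2)), frame.box[:2], [0, 1, 2])


def _true_phase(labeling, truth, leaflet):
    """Planted phase for each labeled marker, joined on (mol_id, atom order)."""
    tm = truth.markers[truth.markers.leaflet == leaflet]
    key_true = {}
    for _, row in tm.iterrows():
        key_true.setdefault(row.mol_id, []).append(row.phase)
    out = []
    seen: dict[int, int] = {}
    for _, row in labeling.iterrows():
        k = seen.get(row.mol_id, 0)
        seen[row.mol_id] = k + 1
        out.append(key_true[row.mol_id][k])
    return np.asarray(out, dtype=object)
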