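"""Heavy-atom contact counting, normalization, regime stratification."""

import numpy as np
import pandas as pd
import pytest
from reference_impl import contact_counts_reference

from monofilm.contacts import (
    contact_preference,
    count_contacts,
    normalize_contacts,
    stratify_by_regime,
)
from monofilm.topology import Frame, Topology, assign_roles


def _system(prot_pos, lipid_specs, box=(10.0, 10.0, 10.0)):
    """Build a minimal topology: CA protein beads + single-atom lipid stand-ins.

    ``lipid_specs`` is a list of (resname, atom_name, xyz).
    """
    resnames, names, mol_ids, positions = [], [], [], []
    mol = 0
    for pos in prot_pos:
        mol += 1
        resnames.append("LEU")
        names.append("CA")
        mol_ids.append(mol)
        positions.append(pos)
    for resname, name, pos in lipid_specs:
        mol += 1
        resnames.append(resname)
        names.append(name)
        mol_ids.append(mol)
        positions.append(pos)
    n = len(positions)
    top = Topology(
        atom_id=np.arange(1, n + 1),
        mol_id=np.asarray(mol_ids),
        resname=np.asarray(resnames, dtype=object),
        atom_name=np.asarray(names, dtype=object),
    )
    from monofilm.topology import ResidueRoles

    config = {
        "DPPC": ResidueRoles("DPPC", "P", (), (), (), "P"),
        "POPC": ResidueRoles("POPC", "P", (), (), (), "P"),
        "POPG": ResidueRoles("POPG", "P", (), (), (), "P"),
        "CHL1": ResidueRoles("CHOL", None, ("C14",), (), (), "O3"),
    }
    # sterol stand-ins would need a C14; use phospholipid stand-ins only
    top = assign_roles(top, config)
    top.leaflet = np.array(["upper"] * top.n_molecules, dtype=object)
    return top, Frame(0.0, np.asarray(box), np.asarray(positions, dtype=float))


class TestCountContacts:
    def test_cutoff_boundary(self):
        for dist, expected in [(0.29, 1), (0.31, 0)]:
            top, frame = _system(
                [[5.0, 5.0, 5.0]], [("DPPC", "P", [5.0 + dist, 5.0, 5.0])]
            )
            raw = count_contacts(frame, top, cutoff=0.3)
            assert raw["contacts"].sum() == expected

    def test_periodic_image_contact(self):
        top, frame = _system([[0.05, 5.0, 5.0]], [("DPPC", "P", [9.85, 5.0, 5.0])])
        raw = count_contacts(frame, top, cutoff=0.3)  # wrapped distance 0.2
        assert raw["contacts"].sum() == 1

    def test_cutoff_beyond_half_box_is_error(self):
        top, frame = _system([[0.5, 0.5, 0.5]], [("DPPC", "P", [0.2, 0.2, 0.2])], box=(1.0, 8.0, 8.0))
        with pytest.raises(ValueError, match="ambiguous"):
            count_contacts(frame, top, cutoff=0.5)

    def test_matches_brute_force_on_random_configuration(self, rng):
        n_prot, n_lip = 100, 400
        box = np.array([6.0, 6.0, 6.0])
        prot = rng.uniform(0, 6, size=(n_prot, 3))
        lipids = rng.uniform(0, 6, size=(n_lip, 3))
        types = rng.choice(["DPPC", "POPC", "POPG"], size=n_lip)
        top, frame = _system(prot, [(t, "P", p) for t, p in zip(types, lipids)], box=box)
        raw = count_contacts(frame, top, cutoff=0.3)
        ref = contact_counts_reference(prot, lipids, box, 0.3)
        assert raw["contacts"].sum() == int(ref.sum())
        # per lipid type as well
        for t in ("DPPC", "POPC", "POPG"):
            ours = raw.loc[raw.lipid_type == t, "contacts"].sum()
            assert ours == int(ref[:, types == t].sum())

    def test_translation_invariance_with_wrap(self, rng):
        box = np.array([6.0, 6.0, 6.0])
        prot = rng.uniform(0, 6, size=(20, 3))
        lipids = rng.uniform(0, 6, size=(80, 3))
        top, frame = _system(prot, [("DPPC", "P", p) for p in lipids], box=box)
        base = count_contacts(frame, top)["contacts"].sum()
        shift = np.array([1.7, -2.9, 0.4])
        frame2 = Frame(0.0, box, np.mod(frame.positions + shift, box))
        assert count_contacts(frame2, top)["contacts"].sum() == base

    def test_residue_sum_equals_total(self, protein_monolayer):
        _, topology, frame, _ = protein_monolayer
        raw = count_contacts(frame, topology)
        per_residue = raw.groupby("residue_id")["contacts"].sum().sum()
        assert per_residue == raw["contacts"].sum()


class TestNormalization:
    def test_equal_raw_counts_twice_abundance_halves_preference(self):
        # 4 POPC atoms vs 2 POPG atoms near the protein, one contact each
        lipids = [("POPC", "P", [5.25, 5.0, 5.0]), ("POPG", "P", [4.75, 5.0, 5.0])]
        lipids += [("POPC", "P", [1.0 + i, 1.0, 1.0]) for i in range(3)]
        lipids += [("POPG", "P", [1.0, 3.0, 1.0])]
        top, frame = _system([[5.0, 5.0, 5.0]], lipids)
        raw = count_contacts(frame, top, cutoff=0.3)
        norm = normalize_contacts(raw, top)
        pref = contact_preference(norm)
        assert pref["POPG"] == pytest.approx(2.0 * pref["POPC"])

    def test_single_lipid_single_contact(self):
        top, frame = _system([[5.0, 5.0, 5.0]], [("DPPC", "P", [5.2, 5.0, 5.0])])
        norm = normalize_contacts(count_contacts(frame, top), top)
        assert norm["normalized"].iloc[0] == pytest.approx(1.0)  # 1 contact / 1 heavy atom

    def test_planted_fourfold_popg_preference_recovered(self, rng):
        # equal POPG and POPC abundance; POPG placed in contact range with
        # 4x the probability of POPC
        box = np.array([12.0, 12.0, 12.0])
        prot = np.array([[6.0, 6.0, 6.0]])
        n_per_type = 2000
        lipids = []
        for resname, p_contact in (("POPG", 0.20), ("POPC", 0.05)):
            in_contact = rng.uniform(size=n_per_type) < p_contact
            for hit in in_contact:
                if hit:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    pos = prot[0] + direction * rng.uniform(0.15, 0.29)
                else:
                    pos = rng.uniform(0, 12, size=3)
                    while np.linalg.norm(pos - prot[0]) < 0.45:
                        pos = rng.uniform(0, 12, size=3)
                lipids.append((resname, "P", pos))
        top, frame = _system(prot, lipids, box=box)
        norm = normalize_contacts(count_contacts(frame, top), top)
        pref = contact_preference(norm)
        ratio = pref["POPG"] / pref["POPC"]
        # binomial sampling error on ~400 and ~100 contacts
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_duplication_scale_equivariance(self):
        lipids = [("DPPC", "P", [5.25, 5.0, 5.0]), ("DPPC", "P", [1.0, 1.0, 1.0])]
        top, frame = _system([[5.0, 5.0, 5.0]], lipids)
        norm1 = contact_preference(normalize_contacts(count_contacts(frame, top), top))
        doubled = lipids + [("DPPC", "P", [5.0, 5.25, 5.0]), ("DPPC", "P", [2.0, 2.0, 2.0])]
        top2, frame2 = _system([[5.0, 5.0, 5.0]], doubled)
        norm2 = contact_preference(normalize_contacts(count_contacts(frame2, top2), top2))
        assert norm2["DPPC"] == pytest.approx(norm1["DPPC"])


class TestStratification:
    @staticmethod
    def _table(c):
        return pd.DataFrame(
            {"residue_id": [1], "residue_name": ["LEU"], "lipid_type": ["POPG"], "contacts": [c]}
        )

    def test_single_regime_equals_mean(self):
        tables = [self._table(c) for c in (2, 4, 6)]
        out = stratify_by_regime(tables, np.array(["low"] * 3, dtype=object))
        assert out["contacts"].iloc[0] == pytest.approx(4.0)

    def test_two_regimes_recover_distinct_plants(self):
        tables = [self._table(c) for c in (2, 10, 2, 10)]
        regimes = np.array(["low", "high", "low", "high"], dtype=object)
        out = stratify_by_regime(tables, regimes).set_index("regime")
        assert out.loc["low", "contacts"] == pytest.approx(2.0)
        assert out.loc["high", "contacts"] == pytest.approx(10.0)

    def test_identical_replicas_have_zero_se(self):
        tables = [self._table(5) for _ in range(4)]
        out = stratify_by_regime(
            tables, np.array(["low"] * 4, dtype=object), replica_per_frame=np.arange(4)
        )
        assert out["contacts_se"].iloc[0] == pytest.approx(0.0)

    def test_frames_outside_all_regimes_dropped(self):
        tables = [self._table(2), self._table(100)]
        out = stratify_by_regime(tables, np.array(["low", None], dtype=object))
        assert out["contacts"].iloc[0] == pytest.approx(2.0)
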