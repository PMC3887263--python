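"""Structure reading, molecule partitioning, H-bond detection, energetics."""

import itertools
import math

import numpy as np
import pytest

import hostguest as hg
from hostguest.structure import BOND_SCALE, COVALENT_RADII, detect_hbonds

WATER_XYZ = """3
water
O 0.000 0.000 0.000
H 0.757 0.586 0.000
H -0.757 0.586 0.000
"""

TWO_WATERS_XYZ = """6
two waters 5 A apart
O 0.000 0.000 0.000
H 0.757 0.586 0.000
H -0.757 0.586 0.000
O 5.000 0.000 0.000
H 5.757 0.586 0.000
H 4.243 0.586 0.000
"""

TWO_CHAIN_PDB = """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.757   0.586   0.000  1.00  0.00           H
ATOM      3  O   HOH B   2       0.500   0.800   0.000  1.00  0.00           O
ATOM      4  H1  HOH B   2       1.257   1.386   0.000  1.00  0.00           H
END
"""


class TestReadStructure:
    def test_water_is_one_molecule(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text(WATER_XYZ)
        s = hg.read_structure(p)
        assert s.n_molecules == 1
        assert [a.element for a in s.atoms] == ["O", "H", "H"]

    def test_separated_waters_are_two_molecules(self, tmp_path):
        p = tmp_path / "ww.xyz"
        p.write_text(TWO_WATERS_XYZ)
        s = hg.read_structure(p)
        assert s.n_molecules == 2
        assert [a.molecule for a in s.atoms] == [1, 1, 1, 2, 2, 2]

    def test_pdb_partition_ignores_chain_labels(self, tmp_path):
        # two "chains" whose atoms are covalently close: geometry wins
        p = tmp_path / "two_chains.pdb"
        p.write_text(TWO_CHAIN_PDB)
        s = hg.read_structure(p)
        assert s.n_molecules == 1

    @pytest.mark.parametrize(
        "content", ["", "not a count\ncomment\n", "2\nc\nO 0 0 0\n"]
    )
    def test_malformed_xyz_rejected(self, tmp_path, content):
        p = tmp_path / "bad.xyz"
        p.write_text(content)
        with pytest.raises(ValueError):
            hg.read_structure(p)

    def test_unknown_extension_rejected(self, tmp_path):
        p = tmp_path / "x.mol2"
        p.write_text("x")
        with pytest.raises(ValueError):
            hg.read_structure(p)


def brute_force_hbonds(s, d_range=(0.8, 2.8), angle_min=120.0, elems={"O", "N"}):
    """Exhaustive triple scan oracle; no neighbor lists, no trees."""
    coords = s.coords
    n = len(s.atoms)

    def bonded(i, j):
        r = COVALENT_RADII[s.atoms[i].element] + COVALENT_RADII[s.atoms[j].element]
        return np.linalg.norm(coords[i] - coords[j]) < BOND_SCALE * r

    found = []
    for d, h, a in itertools.product(range(n), repeat=3):
        if len({d, h, a}) != 3:
            continue
        if s.atoms[h].element != "H" or s.atoms[d].element not in elems:
            continue
        if s.atoms[a].element not in elems:
            continue
        if not bonded(d, h):
            continue
        if s.atoms[a].molecule == s.atoms[h].molecule:
            continue
        dist = float(np.linalg.norm(coords[h] - coords[a]))
        if not d_range[0] <= dist <= d_range[1]:
            continue
        u = coords[d] - coords[h]
        v = coords[a] - coords[h]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        ang = math.degrees(math.acos(max(-1, min(1, cosang))))
        if ang > angle_min:
            found.append((d, h, a, dist, ang))
    return sorted(found)


class TestDetectHbonds:
    def test_planted_geometry_detected_with_exact_values(self):
        truth = hg.GeometryTruth(bonds=((1.902, 158.76, "P=O···H–O"),), seed=0)
        model, _ = hg.plant_hbond_geometry(truth)
        bonds = hg.detect_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].length == pytest.approx(1.902, abs=1e-9)
        assert bonds[0].angle == pytest.approx(158.76, abs=1e-9)
        assert bonds[0].klass == "P=O···H–O"

    def test_distance_outside_range_not_detected(self):
        truth = hg.GeometryTruth(bonds=((2.9, 160.0, "O–H···O"),), seed=0)
        model, _ = hg.plant_hbond_geometry(truth)
        assert hg.detect_hbonds(model) == []

    def test_angle_below_minimum_not_detected(self):
        truth = hg.GeometryTruth(bonds=((1.8, 119.0, "O–H···O"),), seed=0)
        model, _ = hg.plant_hbond_geometry(truth)
        assert hg.detect_hbonds(model) == []

    def test_matches_brute_force_oracle_on_crowded_structure(self):
        from hostguest import reference as ref

        planted = tuple(
            (length, angle, klass)
            for klass, length, angle in ref.ORIENTATION_HBONDS["orientation 1"]
        )
        truth = hg.GeometryTruth(bonds=planted, n_decoys=150, box=40.0, seed=11)
        model, _ = hg.plant_hbond_geometry(truth)
        assert len(model.atoms) <= 200
        fast = [
            (b.donor, b.hydrogen, b.acceptor, b.length, b.angle)
            for b in hg.detect_hbonds(model)
        ]
        oracle = brute_force_hbonds(model)
        assert len(fast) == len(oracle)
        for f, o in zip(sorted(fast), oracle):
            assert f[:3] == o[:3]
            assert f[3] == pytest.approx(o[3], abs=1e-9)
            assert f[4] == pytest.approx(o[4], abs=1e-9)

    def test_no_intramolecular_bonds_reported(self):
        truth = hg.GeometryTruth(
            bonds=tuple((1.7 + 0.1 * i, 150.0 + 5 * i, "O–H···O") for i in range(4)),
            n_decoys=60,
            seed=5,
        )
        model, _ = hg.plant_hbond_geometry(truth)
        for b in hg.detect_hbonds(model):
            assert model.atoms[b.donor].molecule != model.atoms[b.acceptor].molecule


class TestEnergetics:
    def test_orientation_energies(self):
        from hostguest import reference as ref

        de1 = hg.delta_e(ref.ORIENTATION_LEDGERS["orientation 1"])
        de2 = hg.delta_e(ref.ORIENTATION_LEDGERS["orientation 2"])
        assert de1 == pytest.approx(-74.05, abs=1e-9)
        assert de2 == pytest.approx(-60.85, abs=1e-9)

    def test_zero_when_complex_equals_sum(self):
        ledger = hg.EnergyLedger(e_complex=-10.0, e_host=-6.0, e_guest=-4.0)
        assert hg.delta_e(ledger) == pytest.approx(0.0)

    def test_hartree_conversion_commutes_with_subtraction(self):
        h = hg.EnergyLedger(
            e_complex=-5698.812, e_host=-4275.202, e_guest=-1423.492, unit="hartree"
        )
        k = hg.EnergyLedger(
            e_complex=h.e_complex * hg.HARTREE_TO_KCAL,
            e_host=h.e_host * hg.HARTREE_TO_KCAL,
            e_guest=h.e_guest * hg.HARTREE_TO_KCAL,
            unit="kcal/mol",
        )
        assert hg.delta_e(h) == pytest.approx(hg.delta_e(k), abs=1e-6)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            hg.EnergyLedger(1.0, 2.0, 3.0, unit="eV")

    def test_ledger_json_round_trip(self, tmp_path):
        p = tmp_path / "ledger.json"
        p.write_text('{"e_complex": -3.0, "e_host": -1.0, "e_guest": -1.5}')
        assert hg.delta_e(hg.EnergyLedger.from_json(p)) == pytest.approx(-0.5)
        p.write_text('{"e_complex": -3.0, "e_host": -1.0}')
        with pytest.raises(ValueError):
            hg.EnergyLedger.from_json(p)


class TestCompareOrientations:
    def test_ranking_and_difference(self):
        from hostguest import reference as ref

        results = [
            ("orientation 2", hg.delta_e(ref.ORIENTATION_LEDGERS["orientation 2"]),
             [None]),
            ("orientation 1", hg.delta_e(ref.ORIENTATION_LEDGERS["orientation 1"]),
             [None] * 5),
        ]
        report = hg.compare_orientations(results)
        assert report["ranking"][0]["label"] == "orientation 1"
        assert report["ranking"][0]["n_hbonds"] == 5
        assert report["ranking"][1]["n_hbonds"] == 1
        diff = report["pairwise_differences"][0]["difference_kcal"]
        assert diff == pytest.approx(13.20, abs=1e-9)

    def test_equal_energies_keep_stable_label_order(self):
        report = hg.compare_orientations([("b", -1.0, []), ("a", -1.0, [])])
        assert [r["label"] for r in report["ranking"]] == ["a", "b"]

    def test_single_result_rejected(self):
        with pytest.raises(ValueError):
            hg.compare_orientations([("only", -1.0, [])])
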