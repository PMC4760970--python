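import itertools
import math

import numpy as np
import pytest

from rigidmol import (
    InteractionParams,
    Molecule,
    build_network,
    detect_disulfides,
    detect_hydrogen_bonds,
    detect_hydrophobic,
    hydrogen_bond_energy,
    make_fixture,
    perceive_covalent_bonds,
    prune_by_cutoff,
)
from rigidmol.interactions import Interaction, InteractionError, InteractionNetwork
from rigidmol.structure_io import Atom
from rigidmol._data import VDW_RADII


def _shift(molecule, offset):
    atoms = [
        Atom(serial=a.serial, name=a.name, element=a.element,
             alt_loc=a.alt_loc, residue_name=a.residue_name,
             chain_id=a.chain_id, residue_seq=a.residue_seq + offset[3],
             insertion_code=a.insertion_code,
             coords=tuple(np.asarray(a.coords) + np.asarray(offset[:3])))
        for a in molecule.atoms
    ]
    return atoms


def _two_waters(separation):
    """Two waters along x: first donates O-H1 toward the second oxygen."""
    w = make_fixture("water")
    a1 = _shift(w, (0.0, 0.0, 0.0, 0))
    a2 = [
        Atom(serial=a.serial + 3, name=a.name, element=a.element,
             alt_loc="", residue_name=a.residue_name, chain_id=a.chain_id,
             residue_seq=2, insertion_code="",
             coords=tuple(np.asarray(a.coords) + np.array([separation, 0, 0])))
        for a in w.atoms
    ]
    return perceive_covalent_bonds(Molecule(a1 + a2))


def _mayo_reference(d, theta_deg, d0=8.0, r0=2.75):
    """Independent evaluation of the documented closed form."""
    x = r0 / d
    e = d0 * (5 * x**12 - 6 * x**10) * math.cos(math.radians(180 - theta_deg)) ** 2
    return min(0.0, e)


class TestHydrogenBonds:
    def test_distant_waters_have_none(self):
        assert detect_hydrogen_bonds(_two_waters(10.0)) == []

    def test_close_waters_bond(self):
        hbonds = detect_hydrogen_bonds(_two_waters(2.9))
        assert len(hbonds) == 1
        hb = hbonds[0]
        # linear O-H...O: energy equals the independent second
        # implementation of the same closed form
        assert hb.energy == pytest.approx(
            _mayo_reference(hb.geometry_dict["da_distance"],
                            hb.geometry_dict["dha_angle"]))

    def test_helix_has_four_backbone_bonds(self, helix8):
        assert len(detect_hydrogen_bonds(helix8)) == 4

    def test_no_hydrogens_is_explicit_error(self, helix8):
        heavy = Molecule([a for a in helix8.atoms if a.element != "H"])
        with pytest.raises(InteractionError, match="hydrogen"):
            detect_hydrogen_bonds(heavy)

    def test_geometry_reevaluates_to_stored_energy(self, helix8):
        for hb in detect_hydrogen_bonds(helix8):
            assert hydrogen_bond_energy(hb.geometry_dict) == pytest.approx(
                hb.energy)

    def test_rigid_motion_invariance(self, helix8):
        # rotate + translate the whole molecule; energies must not move
        rng = np.random.default_rng(11)
        theta = 0.73
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = rng.uniform(-30, 30, 3)
        atoms = [
            Atom(serial=a.serial, name=a.name, element=a.element,
                 alt_loc=a.alt_loc, residue_name=a.residue_name,
                 chain_id=a.chain_id, residue_seq=a.residue_seq,
                 insertion_code=a.insertion_code,
                 coords=tuple(rot @ np.asarray(a.coords) + shift))
            for a in helix8.atoms
        ]
        moved = perceive_covalent_bonds(Molecule(atoms))
        orig = {hb.triple: hb.energy for hb in detect_hydrogen_bonds(helix8)}
        new = {hb.triple: hb.energy for hb in detect_hydrogen_bonds(moved)}
        assert orig.keys() == new.keys()
        for key in orig:
            assert new[key] == pytest.approx(orig[key], abs=1e-9)


class TestEnergyFunction:
    def test_grid_search_minimum_at_ideal_geometry(self):
        # independent oracle: dense grid over the admissible geometry space
        best = min(
            (_mayo_reference(d, t), round(d, 4), t)
            for d in np.arange(2.3, 3.5, 0.002)
            for t in np.arange(90.0, 180.1, 0.5)
        )
        energy, d_best, t_best = best
        assert t_best == pytest.approx(180.0)
        assert d_best == pytest.approx(2.75, abs=0.01)
        assert hydrogen_bond_energy(
            {"da_distance": 2.75, "dha_angle": 180.0}
        ) == pytest.approx(-8.0)
        assert hydrogen_bond_energy(
            {"da_distance": d_best, "dha_angle": t_best}
        ) == pytest.approx(energy)

    def test_gate_angle_gives_zero(self):
        assert hydrogen_bond_energy(
            {"da_distance": 2.9, "dha_angle": 90.0}) == 0.0

    def test_monotone_in_alignment(self):
        energies = [
            hydrogen_bond_energy({"da_distance": 2.9, "dha_angle": t})
            for t in np.arange(90.0, 180.1, 1.0)
        ]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    def test_outside_gates_is_error(self):
        with pytest.raises(InteractionError):
            hydrogen_bond_energy({"da_distance": 4.2, "dha_angle": 150.0})
        with pytest.raises(InteractionError):
            hydrogen_bond_energy({"da_distance": 2.9, "dha_angle": 45.0})


def _carbon_blob(positions, start_serial=1, start_res=1):
    atoms = []
    for i, (res_off, xyz) in enumerate(positions):
        atoms.append(Atom(
            serial=start_serial + i, name=f"C{i + 1}", element="C",
            alt_loc="", residue_name="LIG", chain_id="A",
            residue_seq=start_res + res_off, insertion_code="",
            coords=tuple(xyz)))
    return Molecule(atoms)


class TestHydrophobic:
    def test_contact_distance(self):
        mol = _carbon_blob([(0, (0, 0, 0)), (1, (3.5, 0, 0))])
        assert len(detect_hydrophobic(mol)) == 1

    def test_far_apart(self):
        mol = _carbon_blob([(0, (0, 0, 0)), (1, (8.0, 0, 0))])
        assert detect_hydrophobic(mol) == []

    def test_three_residues_match_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        positions = [(r, rng.uniform(0, 5, 3)) for r in range(3)
                     for _ in range(3)]
        mol = _carbon_blob(positions)
        got = {(i.atoms, round(i.geometry_dict["distance"], 6))
               for i in detect_hydrophobic(mol)}
        # oracle: exhaustive all-pairs filter then per-residue-pair minimum
        cutoff = 2 * VDW_RADII["C"] + 0.25
        best = {}
        for a, b in itertools.combinations(mol.atoms, 2):
            if a.residue_seq == b.residue_seq:
                continue
            d = float(np.linalg.norm(
                np.asarray(a.coords) - np.asarray(b.coords)))
            if d > cutoff:
                continue
            key = tuple(sorted((a.residue_seq, b.residue_seq)))
            cand = (d, min(a.serial, b.serial), max(a.serial, b.serial))
            if key not in best or cand < best[key]:
                best[key] = cand
        expected = {((sa, sb), round(d, 6)) for d, sa, sb in best.values()}
        assert got == expected


def _cys_pair(distance):
    atoms = []
    for i, x in enumerate((0.0, distance)):
        base = i * 3
        atoms += [
            Atom(serial=base + 1, name="CA", element="C", alt_loc="",
                 residue_name="CYS", chain_id="A", residue_seq=i + 1,
                 insertion_code="", coords=(x, 3.0, 0.0)),
            Atom(serial=base + 2, name="CB", element="C", alt_loc="",
                 residue_name="CYS", chain_id="A", residue_seq=i + 1,
                 insertion_code="", coords=(x, 1.5, 0.0)),
            Atom(serial=base + 3, name="SG", element="S", alt_loc="",
                 residue_name="CYS", chain_id="A", residue_seq=i + 1,
                 insertion_code="", coords=(x, 0.0, 0.0)),
        ]
    return Molecule(atoms)


class TestDisulfides:
    def test_bonded_pair(self):
        assert len(detect_disulfides(_cys_pair(2.05))) == 1

    def test_too_far(self):
        assert detect_disulfides(_cys_pair(4.0)) == []

    def test_three_close_sg_match_exhaustive_scan(self):
        atoms = []
        coords = [(0.0, 0.0, 0.0), (2.1, 0.0, 0.0), (1.05, 1.9, 0.0)]
        for i, xyz in enumerate(coords):
            atoms.append(Atom(
                serial=i + 1, name="SG", element="S", alt_loc="",
                residue_name="CYS", chain_id="A", residue_seq=i + 1,
                insertion_code="", coords=xyz))
        mol = Molecule(atoms)
        got = {i.atoms for i in detect_disulfides(mol)}
        expected = {
            (a.serial, b.serial)
            for a, b in itertools.combinations(atoms, 2)
            if np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)) <= 2.5
        }
        assert got == expected


class TestPruning:
    def _network(self, energies):
        mol = _two_waters(2.9)
        inters = [
            Interaction(kind="hydrogen_bond", atoms=(2, 4), triple=(1, 2, 4),
                        energy=e, geometry=(("da_distance", 2.9),
                                            ("dha_angle", 170.0)))
            for e in energies
        ]
        return InteractionNetwork(mol, inters)

    def test_cutoff_keeps_stronger(self):
        net = prune_by_cutoff(self._network([-3.0, -1.0, -0.2]), -0.5)
        assert len(net.hydrogen_bonds) == 2

    def test_zero_cutoff_is_identity(self):
        net = self._network([-3.0, -1.0, -0.2])
        assert len(prune_by_cutoff(net, 0.0).hydrogen_bonds) == 3

    def test_deep_cutoff_removes_all(self):
        net = self._network([-3.0, -1.0, -0.2])
        assert prune_by_cutoff(net, -10.0).hydrogen_bonds == []

    def test_monotone_in_cutoff(self, helix8):
        net = build_network(helix8)
        cutoffs = [-6.0, -4.0, -1.0, -0.1, 0.0]
        survivors = [
            {i.id for i in prune_by_cutoff(net, c).interactions}
            for c in cutoffs
        ]
        for smaller, larger in zip(survivors, survivors[1:]):
            assert smaller <= larger

    def test_other_kinds_untouched(self, helix8):
        net = build_network(helix8)
        pruned = prune_by_cutoff(net, -100.0)
        assert pruned.by_kind("hydrophobic") == net.by_kind("hydrophobic")
        assert len(net.hydrogen_bonds) == 4  # input unmodified


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        InteractionParams(energy_cutoff=1.0)
    with pytest.raises(ValueError):
        InteractionParams(max_da_distance=-1.0)
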