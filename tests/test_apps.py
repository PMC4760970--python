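import math

import numpy as np
import pytest

from rigidmol import (
    Molecule,
    analyze,
    bond_depth,
    build_network,
    check_refinement,
    classify_redundancy,
    decomposition_signature,
    dilute,
    make_fixture,
    mutate_to_alanine,
    perceive_covalent_bonds,
    prune_by_cutoff,
    rank_mutations,
)
from rigidmol.apps import AppError, MutationResult, dilution_series_to_json, dilution_table
from rigidmol.interactions import Interaction, InteractionNetwork
from rigidmol.structure_io import Atom


@pytest.fixture(scope="module")
def helix_net(helix8):
    return prune_by_cutoff(build_network(helix8), -1.0)


def _shift_water(offset_x, serial0, resseq):
    w = make_fixture("water")
    return [
        Atom(serial=a.serial + serial0, name=a.name, element=a.element,
             alt_loc="", residue_name=a.residue_name, chain_id="A",
             residue_seq=resseq, insertion_code="",
             coords=tuple(np.asarray(a.coords) + np.array([offset_x, 0, 0])))
        for a in w.atoms
    ]


@pytest.fixture()
def water_dimer():
    """Two waters joined by exactly one hydrogen bond."""
    mol = perceive_covalent_bonds(
        Molecule(_shift_water(0, 0, 1) + _shift_water(2.9, 3, 2)))
    return mol, build_network(mol)


class TestDilute:
    def test_series_length(self, helix8, helix_net):
        series = dilute(helix8, helix_net)
        assert len(series.steps) == 5  # step 0 + one per hydrogen bond

    def test_snapshots_match_from_scratch_recomputation(self, helix8, helix_net):
        series = dilute(helix8, helix_net)
        removed = set()
        for t, step in enumerate(series.steps):
            if step.removed is not None:
                removed.add(step.removed)
            fresh = analyze(helix8, helix_net.without(removed))
            assert decomposition_signature(step.decomposition) == \
                decomposition_signature(fresh)

    def test_weakest_first_order(self, helix8, helix_net):
        series = dilute(helix8, helix_net, order="weakest_first")
        energies = [s.energy for s in series.steps[1:]]
        assert energies == sorted(energies, reverse=True)

    def test_strongest_first_order(self, helix8, helix_net):
        series = dilute(helix8, helix_net, order="strongest_first")
        energies = [s.energy for s in series.steps[1:]]
        assert energies == sorted(energies)

    def test_refinement_on_fixture(self, helix8, helix_net):
        for order in ("weakest_first", "strongest_first", "depth"):
            check_refinement(dilute(helix8, helix_net, order=order))

    def test_last_bond_removal_separates_dimer(self, water_dimer):
        # one hinge joins the two waters into a flexible framework of two
        # clusters; removing it leaves them fully disconnected
        mol, net = water_dimer
        assert len(net.hydrogen_bonds) == 1
        series = dilute(mol, net)
        first, final = series.steps[0].decomposition, series.steps[-1].decomposition
        assert len(first.clusters) == 2 and len(first.flexible) == 1
        assert len(final.clusters) == 2 and final.flexible == []

    def test_no_hydrogen_bonds_is_error(self, ethane):
        net = build_network(ethane, detect_hbonds=False)
        with pytest.raises(AppError):
            dilute(ethane, net)

    def test_determinism_byte_identical(self, helix8, helix_net):
        a = dilution_series_to_json(dilute(helix8, helix_net))
        b = dilution_series_to_json(dilute(helix8, helix_net))
        assert a == b

    def test_dilution_table_shape(self, helix8, helix_net):
        series = dilute(helix8, helix_net)
        lines = dilution_table(series, helix8).splitlines()
        assert len(lines) == 1 + len(series.steps)
        assert len(lines[0].split("\t")) == 2 + 8  # 8 residues


class TestBondDepth:
    def _tetrahedron(self, edge=10.0):
        # regular tetrahedron plus two atoms at the centroid
        verts = np.array([
            (1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)
        ], dtype=float) * (edge / (2 * math.sqrt(2)))
        centroid = verts.mean(axis=0)
        coords = list(verts) + [centroid + (0.1, 0, 0), centroid - (0.1, 0, 0)]
        atoms = [
            Atom(serial=i + 1, name=f"C{i + 1}", element="C", alt_loc="",
                 residue_name="LIG", chain_id="A", residue_seq=i + 1,
                 insertion_code="", coords=tuple(c))
            for i, c in enumerate(coords)
        ]
        return Molecule(atoms), verts

    def test_centroid_bond_depth_matches_closed_form(self):
        mol, verts = self._tetrahedron()
        bond = Interaction(kind="hydrophobic", atoms=(5, 6))
        # closed form: centroid-to-face distance of a regular tetrahedron
        # is 1/4 of its height, h = edge * sqrt(2/3)
        edge = float(np.linalg.norm(verts[0] - verts[1]))
        expected = edge * math.sqrt(2.0 / 3.0) / 4.0
        assert bond_depth(mol, bond) == pytest.approx(expected, rel=1e-9)

    def test_bond_on_hull_edge_has_zero_depth(self):
        mol, _verts = self._tetrahedron()
        bond = Interaction(kind="hydrophobic", atoms=(1, 2))
        assert bond_depth(mol, bond) == 0.0

    def test_translation_invariance(self):
        mol, _ = self._tetrahedron()
        bond = Interaction(kind="hydrophobic", atoms=(5, 6))
        moved = Molecule([
            Atom(serial=a.serial, name=a.name, element=a.element, alt_loc="",
                 residue_name=a.residue_name, chain_id=a.chain_id,
                 residue_seq=a.residue_seq, insertion_code="",
                 coords=tuple(np.asarray(a.coords) + np.array([7.0, -3.0, 2.0])))
            for a in mol.atoms
        ])
        assert bond_depth(moved, bond) == pytest.approx(
            bond_depth(mol, bond), abs=1e-9)

    def test_coplanar_molecule_is_error(self, water):
        bond = Interaction(kind="hydrophobic", atoms=(1, 2))
        with pytest.raises(AppError, match="hull"):
            bond_depth(water, bond)


def _leu_variant(helix8, helix_net, residue_seq):
    """Helix variant with one residue relabeled LEU whose methyl is renamed
    CB -> CG (so it counts as side chain beyond C-beta)."""
    rename = {"CB": "CG", "HB1": "HG1", "HB2": "HG2", "HB3": "HG3"}
    atoms = [
        Atom(serial=a.serial,
             name=rename.get(a.name, a.name)
             if a.residue_seq == residue_seq else a.name,
             element=a.element, alt_loc="",
             residue_name="LEU" if a.residue_seq == residue_seq
             else a.residue_name,
             chain_id=a.chain_id, residue_seq=a.residue_seq,
             insertion_code="", coords=a.coords)
        for a in helix8.atoms
    ]
    mol = Molecule(atoms, helix8.bonds)
    return mol, InteractionNetwork(mol, helix_net.interactions)


class TestMutagenesis:
    def test_ala_gly_pro_are_skipped(self, helix8, helix_net):
        result = mutate_to_alanine(helix8, helix_net, None, ("A", 2))
        assert result.skipped and result.score == 0

    def test_residue_without_sidechain_interactions_scores_zero(
            self, helix8, helix_net):
        # plain LEU relabel: every atom name stays within the kept set, so
        # there is nothing beyond C-beta to strip
        atoms = [
            Atom(serial=a.serial, name=a.name, element=a.element, alt_loc="",
                 residue_name="LEU" if a.residue_seq == 4 else a.residue_name,
                 chain_id=a.chain_id, residue_seq=a.residue_seq,
                 insertion_code="", coords=a.coords)
            for a in helix8.atoms
        ]
        mol = Molecule(atoms, helix8.bonds)
        net = InteractionNetwork(mol, helix_net.interactions)
        wt = analyze(mol, net)
        result = mutate_to_alanine(mol, net, None, ("A", 4), wt)
        assert not result.skipped
        assert result.removed == []
        assert result.score == 0
        assert decomposition_signature(result.decomposition) == \
            decomposition_signature(wt)

    def test_mutant_equals_from_scratch_recomputation(self, helix8, helix_net):
        mol, net = _leu_variant(helix8, helix_net, 4)
        wt = analyze(mol, net)
        result = mutate_to_alanine(mol, net, None, ("A", 4), wt)
        assert result.removed  # the renamed methyl carries hydrophobics
        fresh = analyze(mol, net.without(set(result.removed)))
        assert decomposition_signature(result.decomposition) == \
            decomposition_signature(fresh)

    def test_locality_untouched_interactions_survive(self, helix8, helix_net):
        mol, net = _leu_variant(helix8, helix_net, 3)
        result = mutate_to_alanine(mol, net, None, ("A", 3))
        side = {a.serial for a in mol.atoms
                if a.residue_seq == 3 and a.name.endswith(("G", "G1", "G2", "G3"))}
        assert side
        for i in net.interactions:
            participants = set(i.atoms) | set(i.triple or ())
            if not (participants & side):
                assert i.id not in result.removed

    def test_covalent_topology_untouched(self, helix8, helix_net):
        mol, net = _leu_variant(helix8, helix_net, 4)
        result = mutate_to_alanine(mol, net, None, ("A", 4))
        assert all(kind in ("hydrogen_bond", "hydrophobic")
                   for kind, _a, _t in result.removed)

    def test_unknown_residue_is_error(self, helix8, helix_net):
        with pytest.raises(AppError):
            mutate_to_alanine(helix8, helix_net, None, ("A", 99))


class TestRankMutations:
    def _result(self, residue, score, delta):
        return MutationResult(
            residue=("A", residue, ""), residue_name="SER", removed=[],
            decomposition=None, score=score, cluster_count_delta=delta)

    def test_all_zero_preserves_input_order(self):
        results = [self._result(r, 0, 0) for r in (3, 1, 2)]
        ranked = rank_mutations(results, None)
        assert [r.residue[1] for r in ranked] == [3, 1, 2]

    def test_dominant_split_ranks_first(self):
        results = [self._result(1, 0, 0), self._result(2, 40, 3),
                   self._result(3, 5, 1)]
        ranked = rank_mutations(results, None)
        assert [r.residue[1] for r in ranked] == [2, 3, 1]

    def test_matches_bruteforce_sort_oracle(self):
        results = [self._result(1, 5, 2), self._result(2, 5, 4),
                   self._result(3, 9, 0)]
        ranked = rank_mutations(results, None)
        oracle = sorted(results,
                        key=lambda r: (-r.score, -r.cluster_count_delta))
        assert [r.residue for r in ranked] == [r.residue for r in oracle]


class TestRedundancy:
    def test_single_joining_bond_is_critical(self, water_dimer):
        mol, net = water_dimer
        labels = classify_redundancy(mol, net)
        assert list(labels.values()) == ["critical"]

    def test_labels_match_definitional_oracle(self, helix8, helix_net):
        labels = classify_redundancy(helix8, helix_net)
        wt = analyze(helix8, helix_net)
        reference = (decomposition_signature(wt),
                     wt.provenance["free_dof"])
        assert set(labels.values()) == {"redundant", "critical"}
        for bond_id, label in labels.items():
            # independent remove-and-recompute comparison (clusters + DoF)
            dec = analyze(helix8, helix_net.without({bond_id}))
            state = (decomposition_signature(dec),
                     dec.provenance["free_dof"])
            assert (state == reference) == (label == "redundant")

    def test_overconstrained_pair_all_redundant(self):
        # two rigid fragments tied by two hydrogen bonds and a hydrophobic
        # contact: 5+5+3 = 13 > 6 edges, one more than any single removal
        # can drop below rigidity, so every tie is redundant
        frag1 = _shift_water(0, 0, 1)
        frag2 = _shift_water(2.9, 3, 2)
        mol = perceive_covalent_bonds(Molecule(frag1 + frag2))
        net = build_network(mol)
        hb = net.hydrogen_bonds[0]
        extra = [
            Interaction(kind="hydrogen_bond", atoms=(3, 4),
                        triple=(1, 3, 4), energy=-2.0,
                        geometry=(("da_distance", 3.0), ("dha_angle", 150.0))),
            Interaction(kind="hydrophobic", atoms=(1, 4)),
        ]
        strong = InteractionNetwork(mol, net.interactions + extra)
        labels = classify_redundancy(mol, strong)
        assert len(labels) == 3
        assert set(labels.values()) == {"redundant"}
        del hb
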