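"""Derivative rigidity analyses.

Hydrogen-bond dilution (a simplified protein-unfolding model: remove
hydrogen bonds one at a time and watch the rigid clusters break apart),
geometric bond depth, in-silico alanine scanning (strip a residue's
side-chain interactions beyond C-beta and re-analyze), mutation ranking,
and redundancy classification (a bond is redundant iff removing it leaves
the rigid cluster decomposition unchanged — an indicator of structural
over-constraint).

Every step recomputes the decomposition from scratch on the remaining
network; there is no incremental state whose staleness could leak into
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import (
    RigidClusterDecomposition,
    analyze,
    decomposition_signature,
    decomposition_to_json,
)
from .interactions import Interaction, InteractionNetwork
from .mechanics import ModelingOptions
from .structure_io import Molecule
from ._data import ALANINE_KEPT_NAMES, STANDARD_AMINO_ACIDS

__all__ = [
    "DilutionStep",
    "DilutionSeries",
    "MutationResult",
    "AppError",
    "DILUTION_ORDERS",
    "dilute",
    "dilution_table",
    "bond_depth",
    "mutate_to_alanine",
    "rank_mutations",
    "classify_redundancy",
    "match_parent",
    "check_refinement",
    "dilution_series_to_json",
]


class AppError(ValueError):
    pass


DILUTION_ORDERS = ("weakest_first", "strongest_first", "depth")


@dataclass(frozen=True)
class DilutionStep:
    removed: tuple | None          # Interaction.id of the bond removed, None at step 0
    energy: float | None
    decomposition: RigidClusterDecomposition


@dataclass
class DilutionSeries:
    order: str
    steps: list[DilutionStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class MutationResult:
    residue: tuple                  # (chain_id, residue_seq, insertion_code)
    residue_name: str
    removed: list[tuple]
    decomposition: RigidClusterDecomposition | None
    score: int
    cluster_count_delta: int
    skipped: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Hydrogen-bond dilution
# ---------------------------------------------------------------------------

def _dilution_order(molecule: Molecule, hbonds: list[Interaction],
                    order: str) -> list[Interaction]:
    if order == "weakest_first":
        # energy value closest to zero removed first (highest value first)
        return sorted(hbonds, key=lambda i: (-i.energy, i.triple))
    if order == "strongest_first":
        return sorted(hbonds, key=lambda i: (i.energy, i.triple))
    if order == "depth":
        return sorted(hbonds,
                      key=lambda i: (bond_depth(molecule, i), i.triple))
    raise AppError(
        f"unknown dilution order {order!r}; choose from {DILUTION_ORDERS}")


def dilute(molecule: Molecule, network: InteractionNetwork,
           options: ModelingOptions | None = None,
           order: str = "weakest_first") -> DilutionSeries:
    """Remove hydrogen bonds one at a time in the given order, re-running
    the full rigidity analysis after each removal.

    Step 0 is the undiluted decomposition; step t is a from-scratch
    analysis of the network with the first t bonds removed, so each
    snapshot refines its predecessor (removing constraints never creates
    rigidity).
    """
    options = options or ModelingOptions()
    hbonds = network.hydrogen_bonds
    if not hbonds:
        raise AppError("network contains no hydrogen bonds to dilute")
    schedule = _dilution_order(molecule, hbonds, order)

    steps = [DilutionStep(None, None,
                          analyze(molecule, network, options,
                                  provenance={"dilution_step": 0}))]
    current = network
    for t, bond in enumerate(schedule, start=1):
        current = current.without({bond.id})
        steps.append(DilutionStep(
            bond.id, bond.energy,
            analyze(molecule, current, options,
                    provenance={"dilution_step": t}),
        ))
    return DilutionSeries(order=order, steps=steps)


def _residue_label(decomposition: RigidClusterDecomposition,
                   ca_serial: int) -> int:
    labels = [c.label for c in decomposition.clusters if ca_serial in c.atoms]
    return min(labels) if labels else 0


def dilution_table(series: DilutionSeries, molecule: Molecule) -> str:
    """Per-step, per-residue cluster labels (the 1D dilution-plot data).

    Each residue is tracked by its C-alpha atom; the smallest (dominant)
    cluster label containing it is reported, 0 if uncovered.
    """
    residues = []
    for key, name, atoms in molecule.residues():
        if name not in STANDARD_AMINO_ACIDS:
            continue
        ca = next((a.serial for a in atoms if a.name == "CA"), None)
        if ca is not None:
            residues.append((key, ca))
    header = ["step", "removed_energy"] + [
        f"{chain}{seq}{icode}" for (chain, seq, icode), _ca in residues]
    lines = ["\t".join(header)]
    for t, step in enumerate(series.steps):
        energy = f"{step.energy:.4f}" if step.energy is not None else ""
        row = [str(t), energy] + [
            str(_residue_label(step.decomposition, ca))
            for _key, ca in residues]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Geometric bond depth
# ---------------------------------------------------------------------------

def bond_depth(molecule: Molecule, interaction: Interaction) -> float:
    """Depth of a bond inside the molecule: distance from the bond midpoint
    to the nearest facet of the convex hull of all atom coordinates
    (0 for midpoints on or outside the hull).  Rotation- and
    translation-invariant by construction."""
    from scipy.spatial import ConvexHull, QhullError

    coords = molecule.coords_array()
    try:
        hull = ConvexHull(coords)
    except (QhullError, ValueError) as exc:
        raise AppError(
            "convex hull undefined: need at least 4 non-coplanar atoms"
        ) from exc
    a, b = interaction.atoms
    mid = (np.asarray(molecule.atom(a).coords)
           + np.asarray(molecule.atom(b).coords)) / 2.0
    # hull.equations: outward normals n with n·x + d <= 0 inside
    signed = hull.equations[:, :3] @ mid + hull.equations[:, 3]
    return float(max(0.0, -signed.max()))


# ---------------------------------------------------------------------------
# Alanine scanning
# ---------------------------------------------------------------------------

def _side_chain_serials(molecule: Molecule, residue_key: tuple) -> set[int]:
    return {a.serial for a in molecule.atoms
            if a.residue_key == residue_key
            and a.name not in ALANINE_KEPT_NAMES}


def mutate_to_alanine(molecule: Molecule, network: InteractionNetwork,
                      options: ModelingOptions | None,
                      residue: tuple,
                      wild_type: RigidClusterDecomposition | None = None
                      ) -> MutationResult:
    """Simulated point mutation to alanine.

    ``residue`` is (chain_id, residue_seq) or (chain_id, residue_seq,
    insertion_code).  All hydrogen bonds and hydrophobic contacts with at
    least one participant in the residue's side chain beyond C-beta are
    removed and the decomposition recomputed; the covalent topology is left
    untouched.  GLY/ALA/PRO are skipped with a warning result (no side
    chain to strip, or a backbone-fused ring).
    """
    options = options or ModelingOptions()
    if len(residue) == 2:
        residue = (residue[0], residue[1], "")
    res_atoms = [a for a in molecule.atoms if a.residue_key == residue]
    if not res_atoms:
        raise AppError(f"no residue {residue} in molecule")
    resname = res_atoms[0].residue_name
    if resname not in STANDARD_AMINO_ACIDS:
        raise AppError(
            f"residue {residue} is {resname}, not a standard amino acid")
    if wild_type is None:
        wild_type = analyze(molecule, network, options)
    if resname in ("GLY", "ALA", "PRO"):
        return MutationResult(
            residue=residue, residue_name=resname, removed=[],
            decomposition=None, score=0, cluster_count_delta=0,
            skipped=True,
            note=f"{resname} is not subject to alanine substitution",
        )
    side = _side_chain_serials(molecule, residue)
    removed = []
    for inter in network.interactions:
        if inter.kind not in ("hydrogen_bond", "hydrophobic"):
            continue
        participants = set(inter.atoms) | set(inter.triple or ())
        if participants & side:
            removed.append(inter.id)
    mutant_net = network.without(set(removed))
    mutant = analyze(molecule, mutant_net, options,
                     provenance={"mutation": list(residue)})
    return MutationResult(
        residue=residue, residue_name=resname, removed=sorted(removed),
        decomposition=mutant,
        score=wild_type.largest_size() - mutant.largest_size(),
        cluster_count_delta=len(mutant.clusters) - len(wild_type.clusters),
    )


def rank_mutations(results: list[MutationResult],
                   wild_type: RigidClusterDecomposition
                   ) -> list[MutationResult]:
    """Most destabilizing first: by shrinkage of the dominant cluster, then
    by increase in cluster count; equal scores keep input (residue) order."""
    del wild_type  # scores were computed against it; kept for the contract
    return sorted(results,
                  key=lambda r: (-r.score, -r.cluster_count_delta))


# ---------------------------------------------------------------------------
# Redundancy classification
# ---------------------------------------------------------------------------

def classify_redundancy(molecule: Molecule, network: InteractionNetwork,
                        options: ModelingOptions | None = None
                        ) -> dict[tuple, str]:
    """Label every non-covalent interaction redundant or critical.

    The definition is applied literally: remove the bond, recompute from
    scratch, and compare with the reference — both the cluster atom sets
    and the framework's free degrees of freedom.  The DoF term matters:
    a lone hinge between two otherwise-free clusters leaves the cluster
    list unchanged when removed, yet it carries independent constraints
    and the structure visibly loosens, so it must count as critical.
    """
    options = options or ModelingOptions()
    reference = _redundancy_state(analyze(molecule, network, options))
    covalent_pairs = {b.pair for b in molecule.bonds}
    labels: dict[tuple, str] = {}
    for inter in network.interactions:
        if inter.kind not in ("hydrogen_bond", "hydrophobic", "disulfide"):
            continue
        if inter.kind == "disulfide" and inter.atoms in covalent_pairs:
            continue  # part of the covalent skeleton, not removable here
        reduced = network.without({inter.id})
        state = _redundancy_state(analyze(molecule, reduced, options))
        labels[inter.id] = "redundant" if state == reference else "critical"
    return labels


def _redundancy_state(decomposition: RigidClusterDecomposition):
    return (decomposition_signature(decomposition),
            decomposition.provenance.get("free_dof"))


# ---------------------------------------------------------------------------
# Refinement checking (shared with coloring)
# ---------------------------------------------------------------------------

def match_parent(previous: RigidClusterDecomposition,
                 cluster) -> tuple[int | None, bool]:
    """Find the step-earlier cluster a child came from.

    Returns (parent label, contained) where the parent is the previous
    cluster sharing the most atoms (ties to the smaller label) and
    ``contained`` says whether the child's atoms are a subset of the
    parent's, up to atoms the parent already shared with other clusters
    (hinge-axis overlap)."""
    best_label, best_shared = None, 0
    for prev in previous.clusters:
        shared = len(prev.atoms & cluster.atoms)
        if shared > best_shared:
            best_label, best_shared = prev.label, shared
    if best_label is None:
        return None, False
    parent = previous.clusters[best_label - 1]
    extra = cluster.atoms - parent.atoms
    if extra:
        shared_elsewhere: set[int] = set()
        for prev in previous.clusters:
            if prev.label != best_label:
                shared_elsewhere |= (prev.atoms & cluster.atoms)
        contained = extra <= shared_elsewhere and len(extra) <= 2
    else:
        contained = True
    return best_label, contained


def check_refinement(series: DilutionSeries) -> None:
    """Raise AppError naming the first step whose snapshot does not refine
    its predecessor."""
    for t in range(1, len(series.steps)):
        prev = series.steps[t - 1].decomposition
        cur = series.steps[t].decomposition
        for c in cur.clusters:
            _parent, contained = match_parent(prev, c)
            if not contained:
                raise AppError(
                    f"dilution step {t}: cluster {c.label} is not contained "
                    f"in any step-{t - 1} cluster")


def dilution_series_to_json(series: DilutionSeries) -> str:
    import json

    doc = {
        "order": series.order,
        "steps": [
            {
                "removed": list(map(str, s.removed)) if s.removed else None,
                "energy": s.energy,
                "decomposition": json.loads(
                    decomposition_to_json(s.decomposition)),
            }
            for s in series.steps
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)
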