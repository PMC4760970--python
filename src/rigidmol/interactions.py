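"""Non-covalent interaction detection and energy scoring.

Builds the typed bond network consumed by mechanical modeling: covalent
bonds imported from the molecule, hydrogen bonds scored with an explicit
Mayo-style distance–angle energy, hydrophobic contacts between apolar
carbon/sulfur atoms, and disulfide bridges.  Hydrogen bonds can be pruned
by an energy cutoff — the primary tunable knob of the whole analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._data import DEFAULT_VDW_RADIUS, VDW_RADII
from .structure_io import Molecule

__all__ = [
    "Interaction",
    "InteractionParams",
    "InteractionNetwork",
    "InteractionError",
    "detect_hydrogen_bonds",
    "hydrogen_bond_energy",
    "detect_hydrophobic",
    "detect_disulfides",
    "build_network",
    "prune_by_cutoff",
    "network_to_tsv",
]

NONCOVALENT_KINDS = ("hydrogen_bond", "hydrophobic")
COVALENT_KINDS = ("covalent_single", "covalent_double", "peptide", "disulfide")

_BOND_ORDER_TO_KIND = {
    "single": "covalent_single",
    "double": "covalent_double",
    "peptide": "peptide",
    "disulfide": "disulfide",
}


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class Interaction:
    """One typed bond or interaction between two atoms (by serial).

    For hydrogen bonds, ``atoms`` is the (hydrogen, acceptor) contact that
    acts as the mechanical axis, and ``triple`` carries the full
    (donor, hydrogen, acceptor).  Energies (kcal/mol) are present exactly
    for hydrogen bonds; geometry records the distances/angles the energy
    was computed from.
    """

    kind: str
    atoms: tuple[int, int]
    triple: tuple[int, int, int] | None = None
    energy: float | None = None
    geometry: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.atoms[0] == self.atoms[1]:
            raise ValueError("interaction endpoints must be distinct")
        if self.kind == "hydrogen_bond" and self.energy is None:
            raise ValueError("hydrogen bonds must carry an energy")

    @property
    def id(self) -> tuple:
        return (self.kind, self.atoms, self.triple)

    @property
    def geometry_dict(self) -> dict[str, float]:
        return dict(self.geometry)


@dataclass
class InteractionParams:
    """Geometric gates and energy constants.

    max_da_distance   donor–acceptor distance gate (Å)
    min_dha_angle     donor–hydrogen–acceptor angle gate (degrees)
    hydrophobic_slack added to summed vdW radii for C/S contacts (Å)
    energy_cutoff     hydrogen bonds weaker (greater) than this are pruned
                      (kcal/mol; the main tunable of the analysis)
    well_depth, r0    Mayo-style well depth (kcal/mol) and optimum
                      donor–acceptor distance (Å)
    exclusion_bonds   donor/acceptor (or C/S) pairs closer than this many
                      covalent bonds are never counted as interactions
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 90.0
    hydrophobic_slack: float = 0.25
    energy_cutoff: float = -1.0
    well_depth: float = 8.0
    r0: float = 2.75
    exclusion_bonds: int = 3

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.r0 <= 0:
            raise ValueError("distances must be positive")
        if self.energy_cutoff > 0:
            raise ValueError("energy cutoff must be <= 0 kcal/mol")


@dataclass
class InteractionNetwork:
    """The molecule together with its typed interaction list."""

    molecule: Molecule
    interactions: list[Interaction] = field(default_factory=list)

    def by_kind(self, *kinds: str) -> list[Interaction]:
        return [i for i in self.interactions if i.kind in kinds]

    @property
    def hydrogen_bonds(self) -> list[Interaction]:
        return self.by_kind("hydrogen_bond")

    def without(self, drop: set) -> "InteractionNetwork":
        """New network with the interactions whose ids are in ``drop`` removed."""
        return InteractionNetwork(
            self.molecule,
            [i for i in self.interactions if i.id not in drop],
        )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hydrogen_bond_energy(geometry: dict[str, float],
                         params: InteractionParams | None = None) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol) from a geometry record.

    E = D0 · [5 (R0/d)^12 − 6 (R0/d)^10] · cos²(180° − θ)

    with d the donor–acceptor distance, θ the D–H···A angle, D0 the well
    depth and R0 the optimum distance.  The global minimum −D0 is attained
    at d = R0, θ = 180°; the angular factor vanishes at the 90° gate.  The
    value is clamped at 0 from above so that admissible geometry never
    scores a positive (repulsive) energy.
    """
    params = params or InteractionParams()
    d = geometry["da_distance"]
    theta = geometry["dha_angle"]
    if not (0 < d <= params.max_da_distance):
        raise InteractionError(
            f"donor–acceptor distance {d:.2f} Å outside the "
            f"(0, {params.max_da_distance}] gate")
    if not (params.min_dha_angle <= theta <= 180.0):
        raise InteractionError(
            f"D–H–A angle {theta:.1f}° outside the "
            f"[{params.min_dha_angle}, 180] gate")
    x = params.r0 / d
    radial = 5.0 * x**12 - 6.0 * x**10
    # sin²(θ−90°) ≡ cos²(180°−θ), but evaluates to exactly 0 at the gate
    angular = math.sin(math.radians(theta - 90.0)) ** 2
    return min(0.0, params.well_depth * radial * angular)


def _bond_distances_within(molecule: Molecule, sources: set[int],
                           max_depth: int) -> dict[int, dict[int, int]]:
    """BFS covalent-path lengths from each source, truncated at max_depth."""
    adj = molecule.neighbors()
    out: dict[int, dict[int, int]] = {}
    for s in sources:
        dist = {s: 0}
        frontier = [s]
        for depth in range(1, max_depth + 1):
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = depth
                        nxt.append(w)
            frontier = nxt
        out[s] = dist
    return out


def detect_hydrogen_bonds(molecule: Molecule,
                          params: InteractionParams | None = None
                          ) -> list[Interaction]:
    """Find all (donor, hydrogen, acceptor) triples passing the gates.

    Donors are N/O with a covalently attached hydrogen; acceptors are N/O.
    Pairs separated by at most ``params.exclusion_bonds`` covalent bonds are
    skipped (they are part of the covalent skeleton, not hydrogen bonds).
    Raises if the molecule carries no hydrogens at all: hydrogen placement
    is a prerequisite of the analysis, and silence would hide that.
    """
    params = params or InteractionParams()
    if not any(a.element.upper() == "H" for a in molecule.atoms):
        raise InteractionError(
            "molecule has no hydrogen atoms; hydrogen-bond detection "
            "requires a protonated structure")
    adj = molecule.neighbors()
    donors = [
        (a.serial, h)
        for a in molecule.atoms if a.element.upper() in ("N", "O")
        for h in sorted(adj[a.serial])
        if molecule.atom(h).element.upper() == "H"
    ]
    acceptors = [a.serial for a in molecule.atoms
                 if a.element.upper() in ("N", "O")]
    if not donors or not acceptors:
        return []
    pos = {a.serial: np.asarray(a.coords) for a in molecule.atoms}
    excl = _bond_distances_within(
        molecule, {d for d, _h in donors}, params.exclusion_bonds)

    from scipy.spatial import cKDTree
    acc_pos = np.array([pos[a] for a in acceptors])
    tree = cKDTree(acc_pos)

    found: dict[tuple[int, int, int], Interaction] = {}
    for d_serial, h_serial in donors:
        for idx in tree.query_ball_point(pos[d_serial], params.max_da_distance):
            a_serial = acceptors[idx]
            if a_serial == d_serial or a_serial in excl[d_serial]:
                continue
            da = float(np.linalg.norm(pos[d_serial] - pos[a_serial]))
            v1 = pos[d_serial] - pos[h_serial]
            v2 = pos[a_serial] - pos[h_serial]
            cosang = float(np.dot(v1, v2)
                           / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if theta < params.min_dha_angle:
                continue
            geometry = (
                ("da_distance", round(da, 6)),
                ("ha_distance",
                 round(float(np.linalg.norm(v2)), 6)),
                ("dha_angle", round(theta, 6)),
            )
            energy = hydrogen_bond_energy(dict(geometry), params)
            key = (d_serial, h_serial, a_serial)
            found[key] = Interaction(
                kind="hydrogen_bond",
                atoms=(h_serial, a_serial),
                triple=key,
                energy=energy,
                geometry=geometry,
            )
    return [found[k] for k in sorted(found)]


# ---------------------------------------------------------------------------
# Hydrophobic contacts and disulfides
# ---------------------------------------------------------------------------

def detect_hydrophobic(molecule: Molecule,
                       params: InteractionParams | None = None
                       ) -> list[Interaction]:
    """Carbon/sulfur contacts between residues, deduplicated per residue pair.

    A pair qualifies when d ≤ r_vdw(a) + r_vdw(b) + slack, the atoms sit in
    different residues, and they are covalently distant; only the closest
    contact per residue pair is kept, so a single packed interface never
    inflates the bar count.
    """
    params = params or InteractionParams()
    apolar = [a for a in molecule.atoms if a.element.upper() in ("C", "S")]
    if len(apolar) < 2:
        return []
    pos = np.array([a.coords for a in apolar])
    radii = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS)
                      for a in apolar])
    excl = _bond_distances_within(
        molecule, {a.serial for a in apolar}, params.exclusion_bonds)

    from scipy.spatial import cKDTree
    tree = cKDTree(pos)
    best: dict[tuple, tuple[float, int, int]] = {}
    for i, j in tree.query_pairs(float(2 * radii.max() + params.hydrophobic_slack)):
        ai, aj = apolar[i], apolar[j]
        if ai.residue_key == aj.residue_key:
            continue
        if aj.serial in excl[ai.serial]:
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d > radii[i] + radii[j] + params.hydrophobic_slack:
            continue
        key = tuple(sorted((ai.residue_key, aj.residue_key)))
        cand = (d, min(ai.serial, aj.serial), max(ai.serial, aj.serial))
        if key not in best or cand < best[key]:
            best[key] = cand
    out = []
    for key in sorted(best):
        d, sa, sb = best[key]
        out.append(Interaction(
            kind="hydrophobic", atoms=(sa, sb),
            geometry=(("distance", round(d, 6)),),
        ))
    return out


def detect_disulfides(molecule: Molecule,
                      max_distance: float = 2.5) -> list[Interaction]:
    """SG–SG pairs of distinct cysteines within ``max_distance`` Å."""
    sgs = [a for a in molecule.atoms
           if a.name == "SG" and a.residue_name == "CYS"]
    out = []
    for i, a in enumerate(sgs):
        for b in sgs[i + 1:]:
            if a.residue_key == b.residue_key:
                continue
            d = float(np.linalg.norm(
                np.asarray(a.coords) - np.asarray(b.coords)))
            if d <= max_distance:
                out.append(Interaction(
                    kind="disulfide",
                    atoms=(min(a.serial, b.serial), max(a.serial, b.serial)),
                    geometry=(("distance", round(d, 6)),),
                ))
    return out


# ---------------------------------------------------------------------------
# Network assembly and pruning
# ---------------------------------------------------------------------------

def build_network(molecule: Molecule,
                  params: InteractionParams | None = None,
                  detect_hbonds: bool = True) -> InteractionNetwork:
    """Assemble the full unpruned interaction network.

    Covalent bonds are imported as interactions; hydrogen bonds,
    hydrophobic contacts, and disulfides are detected geometrically.
    Detected disulfides replace nothing — if the SG–SG bond is already
    covalent (CONECT/SSBOND-derived), the geometric detection is skipped
    for that pair.
    """
    params = params or InteractionParams()
    interactions: list[Interaction] = []
    covalent_pairs = set()
    for b in molecule.bonds:
        covalent_pairs.add((b.a, b.b))
        interactions.append(Interaction(
            kind=_BOND_ORDER_TO_KIND[b.order], atoms=(b.a, b.b)))
    for ss in detect_disulfides(molecule):
        if ss.atoms not in covalent_pairs:
            interactions.append(ss)
    if detect_hbonds:
        interactions.extend(detect_hydrogen_bonds(molecule, params))
    interactions.extend(detect_hydrophobic(molecule, params))
    return InteractionNetwork(molecule, interactions)


def prune_by_cutoff(network: InteractionNetwork,
                    cutoff: float) -> InteractionNetwork:
    """Drop hydrogen bonds weaker than ``cutoff`` (energy > cutoff).

    All other interaction kinds pass through untouched; the input network
    is not modified.
    """
    kept = [i for i in network.interactions
            if i.kind != "hydrogen_bond" or i.energy <= cutoff]
    return InteractionNetwork(network.molecule, kept)


def network_to_tsv(network: InteractionNetwork) -> str:
    """Tab-separated export: kind, atom serials, energy, geometry fields."""
    lines = ["kind\tatom_a\tatom_b\tdonor\thydrogen\tacceptor\tenergy\tgeometry"]
    for i in network.interactions:
        d, h, a = i.triple if i.triple else ("", "", "")
        energy = f"{i.energy:.6f}" if i.energy is not None else ""
        geom = ";".join(f"{k}={v:g}" for k, v in i.geometry)
        lines.append(
            f"{i.kind}\t{i.atoms[0]}\t{i.atoms[1]}\t{d}\t{h}\t{a}\t{energy}\t{geom}"
        )
    return "\n".join(lines) + "\n"
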