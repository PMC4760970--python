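"""Atom-level rigid cluster decomposition.

Converts pebble-game components back to clusters of atoms connected by
bonds.  Because adjacent bodies overlap on the two atoms of their shared
bond, two clusters may likewise share exactly the two atoms of a hinge
axis — clusters are not forced to be disjoint.  Also provides decomposition
summaries, JSON/TSV serialization, and shared-atom overlap matrices for
comparing two decompositions of the same molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .interactions import InteractionNetwork, InteractionParams, build_network, prune_by_cutoff
from .mechanics import BodyBarHingeModel, ModelingOptions, build_model, to_multigraph
from .pebble import PebbleParams, PebbleResult, free_dof, run_pebble_game
from .structure_io import Molecule

__all__ = [
    "RigidCluster",
    "RigidClusterDecomposition",
    "ClusterError",
    "components_to_clusters",
    "summarize",
    "overlap_matrix",
    "analyze",
    "analyze_molecule",
    "decomposition_to_json",
    "decomposition_from_json",
    "decomposition_to_tsv",
    "decomposition_signature",
]


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class RigidCluster:
    """One rigid cluster: a set of atoms (and the bodies they came from).

    label 1 is the largest cluster; equal sizes are ordered by their
    smallest atom serial so labels are deterministic.
    """

    label: int
    atoms: frozenset[int]
    bodies: frozenset[int]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("cluster must contain at least one atom")

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class RigidClusterDecomposition:
    """Ordered cluster list plus the flexible joints between clusters."""

    clusters: list[RigidCluster]
    flexible: list[tuple[int, int, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def atom_universe(self) -> frozenset[int]:
        out: set[int] = set()
        for c in self.clusters:
            out |= c.atoms
        return frozenset(out)

    def largest_size(self) -> int:
        return self.clusters[0].size if self.clusters else 0


def _order_clusters(atom_sets: list[tuple[frozenset[int], frozenset[int]]]
                    ) -> list[RigidCluster]:
    ordered = sorted(atom_sets, key=lambda ab: (-len(ab[0]), min(ab[0])))
    return [RigidCluster(label=i + 1, atoms=atoms, bodies=bodies)
            for i, (atoms, bodies) in enumerate(ordered)]


def components_to_clusters(result: PebbleResult,
                           model: BodyBarHingeModel,
                           provenance: dict | None = None
                           ) -> RigidClusterDecomposition:
    """Map each multigraph component to the union of its bodies' atoms.

    Bodies belonging to no component become trivial single-body clusters,
    so every atom covered by a body appears in at least one cluster.
    Connections joining bodies of different clusters are inherited as the
    flexible joints of the decomposition.
    """
    body_ids = {b.id for b in model.bodies}
    if set(result.free_pebbles) != body_ids:
        raise ClusterError(
            "pebble result does not match this model: vertex set differs")

    by_id = {b.id: b for b in model.bodies}
    body_to_cluster: dict[int, int] = {}
    atom_sets: list[tuple[frozenset[int], frozenset[int]]] = []
    for comp in result.components:
        atoms: set[int] = set()
        for bid in comp:
            atoms |= by_id[bid].atoms
        atom_sets.append((frozenset(atoms), frozenset(comp)))
    in_comp = set().union(*result.components) if result.components else set()
    for b in model.bodies:
        if b.id not in in_comp:
            atom_sets.append((b.atoms, frozenset({b.id})))

    clusters = _order_clusters(atom_sets)
    for c in clusters:
        for bid in c.bodies:
            body_to_cluster[bid] = c.label

    flexible: list[tuple[int, int, str]] = []
    for conn in model.connections:
        la, lb = body_to_cluster[conn.bodies[0]], body_to_cluster[conn.bodies[1]]
        if la != lb:
            kind = conn.source[0]
            flexible.append((min(la, lb), max(la, lb), kind))
    flexible.sort()
    return RigidClusterDecomposition(
        clusters=clusters, flexible=flexible,
        provenance=dict(provenance or {}),
    )


def summarize(decomposition: RigidClusterDecomposition) -> dict:
    """Headline numbers: cluster count, largest size, coverage, joints."""
    return {
        "cluster_count": len(decomposition.clusters),
        "largest_cluster_size": decomposition.largest_size(),
        "atom_coverage": len(decomposition.atom_universe),
        "flexible_connection_count": len(decomposition.flexible),
    }


def overlap_matrix(a: RigidClusterDecomposition,
                   b: RigidClusterDecomposition) -> np.ndarray:
    """Entry (i, j) = number of atoms shared by a's cluster i+1 and b's
    cluster j+1."""
    if not (a.atom_universe & b.atom_universe):
        raise ClusterError("decompositions share no atoms")
    mat = np.zeros((len(a.clusters), len(b.clusters)), dtype=int)
    for i, ca in enumerate(a.clusters):
        for j, cb in enumerate(b.clusters):
            mat[i, j] = len(ca.atoms & cb.atoms)
    return mat


def decomposition_signature(decomposition: RigidClusterDecomposition):
    """Order-free identity of a decomposition: the multiset of cluster atom
    sets.  Two decompositions are 'the same' iff signatures are equal."""
    return tuple(sorted(
        (tuple(sorted(c.atoms)) for c in decomposition.clusters)))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def analyze(molecule: Molecule, network: InteractionNetwork,
            options: ModelingOptions | None = None,
            pebble_params: PebbleParams | None = None,
            provenance: dict | None = None) -> RigidClusterDecomposition:
    """Run the complete rigidity analysis on a prepared network:
    bodies -> connections -> multigraph -> pebble game -> clusters."""
    options = options or ModelingOptions()
    model = build_model(molecule, network, options)
    graph = to_multigraph(model)
    result = run_pebble_game(graph, pebble_params)
    prov = {"options": {k: v for k, v in sorted(options.models.items())}}
    if result.free_pebbles:
        prov["free_dof"] = free_dof(result)
    prov.update(provenance or {})
    return components_to_clusters(result, model, prov)


def analyze_molecule(molecule: Molecule,
                     params: InteractionParams | None = None,
                     options: ModelingOptions | None = None
                     ) -> RigidClusterDecomposition:
    """Convenience front door: detect interactions, prune by the energy
    cutoff in ``params``, and analyze."""
    params = params or InteractionParams()
    network = prune_by_cutoff(build_network(molecule, params),
                              params.energy_cutoff)
    return analyze(molecule, network, options,
                   provenance={"cutoff": params.energy_cutoff})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def decomposition_to_json(decomposition: RigidClusterDecomposition) -> str:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "provenance": decomposition.provenance,
        "clusters": [
            {
                "label": c.label,
                "size": c.size,
                "atom_serials": sorted(c.atoms),
                "body_ids": sorted(c.bodies),
            }
            for c in decomposition.clusters
        ],
        "flexible": [
            {"clusters": [la, lb], "kind": kind}
            for la, lb, kind in decomposition.flexible
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def decomposition_from_json(text: str) -> RigidClusterDecomposition:
    doc = json.loads(text)
    clusters = [
        RigidCluster(label=d["label"], atoms=frozenset(d["atom_serials"]),
                     bodies=frozenset(d.get("body_ids", ())))
        for d in doc["clusters"]
    ]
    clusters.sort(key=lambda c: c.label)
    flexible = [(d["clusters"][0], d["clusters"][1], d["kind"])
                for d in doc.get("flexible", ())]
    return RigidClusterDecomposition(clusters, flexible,
                                     doc.get("provenance", {}))


def decomposition_to_tsv(decomposition: RigidClusterDecomposition) -> str:
    """Flat per-atom table: atom serial -> comma-joined cluster labels
    (an atom on a hinge axis belongs to two clusters)."""
    membership: dict[int, list[int]] = {}
    for c in decomposition.clusters:
        for s in c.atoms:
            membership.setdefault(s, []).append(c.label)
    lines = ["atom_serial\tcluster_labels"]
    for s in sorted(membership):
        lines.append(f"{s}\t{','.join(str(x) for x in sorted(membership[s]))}")
    return "\n".join(lines) + "\n"
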