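"""Body-bar-hinge mechanical modeling and multigraph construction.

Atoms with two or more covalent neighbors become rigid bodies (the atom
plus all its neighbors, so adjacent bodies overlap on the two atoms of the
bond between them).  Each remaining interaction joins two bodies either as
a hinge — a shared rotation axis, removing 5 of the 6 relative degrees of
freedom — or as b ∈ [1, 6] bars.  The multigraph for the pebble game gets
one vertex per body, 5 parallel edges per hinge, and b edges per bar
connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .interactions import Interaction, InteractionNetwork
from .structure_io import Molecule

__all__ = [
    "Body",
    "Connection",
    "ModelingOptions",
    "BodyBarHingeModel",
    "Multigraph",
    "ModelingError",
    "build_bodies",
    "assign_connections",
    "build_model",
    "to_multigraph",
    "multigraph_to_edge_list",
    "multigraph_from_edge_list",
]

HINGE = "hinge"
EDGES_PER_HINGE = 5  # a hinge leaves exactly one relative DoF in 3D


class ModelingError(ValueError):
    pass


@dataclass(frozen=True)
class Body:
    """A group of atoms known a priori to move as one rigid unit."""

    id: int
    atoms: frozenset[int]
    kind: str = "atom_hub"
    hub: int | None = None  # central atom serial for atom_hub bodies

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("body must contain at least one atom")
        if self.hub is not None and self.hub not in self.atoms:
            raise ValueError("hub atom must belong to its body")


@dataclass(frozen=True)
class Connection:
    """A mechanical joint between two distinct bodies.

    model is either "hinge" or an integer bar count in [1, 6]; hinges carry
    the bonded atom pair that acts as the rotation axis.
    """

    id: int
    bodies: tuple[int, int]
    model: str | int
    source: tuple  # Interaction.id of the interaction that produced it
    axis: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.bodies[0] == self.bodies[1]:
            raise ValueError("connection must join two distinct bodies")
        if self.model != HINGE:
            if not isinstance(self.model, int) or not 1 <= self.model <= 6:
                raise ModelingError(
                    f"bar count must be an integer in [1, 6], got {self.model!r}")
        elif self.axis is None:
            raise ValueError("hinge connection requires an axis atom pair")

    @property
    def edge_count(self) -> int:
        return EDGES_PER_HINGE if self.model == HINGE else self.model


@dataclass
class ModelingOptions:
    """Map from interaction kind to its mechanical model.

    Defaults follow the standard molecular modeling convention: rotatable
    covalent bonds, disulfides and hydrogen bonds are hinges; peptide and
    double bonds are locked (6 bars); hydrophobic contacts contribute 3
    bars (they restrict sliding but not all relative motion).
    """

    models: dict[str, str | int] = field(default_factory=lambda: {
        "covalent_single": HINGE,
        "covalent_double": 6,
        "peptide": 6,
        "disulfide": HINGE,
        "hydrogen_bond": HINGE,
        "hydrophobic": 3,
    })

    def __post_init__(self) -> None:
        for kind, model in self.models.items():
            if model != HINGE and (
                    not isinstance(model, int) or not 1 <= model <= 6):
                raise ModelingError(
                    f"model for {kind!r} must be 'hinge' or an integer "
                    f"bar count in [1, 6], got {model!r}")

    def model_for(self, kind: str) -> str | int:
        if kind not in self.models:
            raise ModelingError(f"no mechanical model for kind {kind!r}")
        return self.models[kind]


@dataclass
class BodyBarHingeModel:
    bodies: list[Body]
    connections: list[Connection]
    molecule: Molecule
    network: InteractionNetwork
    internal: list[tuple] = field(default_factory=list)  # skipped interactions

    def body_of_atom(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for b in self.bodies:
            for s in b.atoms:
                out.setdefault(s, []).append(b.id)
        return out


@dataclass
class Multigraph:
    """Loop-free multigraph: vertices are body ids, parallel edges allowed.

    Each edge is (u, v, tag) with u < v; the tag is the id of the source
    connection, so edges from one hinge form a group of 5 sharing a tag.
    """

    vertices: list[int]
    edges: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        for u, v, _t in self.edges:
            if u == v:
                raise ValueError("loops are not admissible")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u},{v}) references missing vertex")
        self.edges = [(min(u, v), max(u, v), t) for u, v, t in self.edges]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_bodies(molecule: Molecule) -> list[Body]:
    """Assign rigid bodies: one hub body per atom of covalent degree >= 2,
    containing the atom and all its covalent neighbors.

    Adjacent hub bodies overlap on the two atoms of their shared bond — the
    future hinge axis.  Atoms of degree <= 1 live only inside their
    neighbor's body; isolated atoms and bonded pairs of degree-1 atoms
    become their own (singleton/diatomic) bodies so every atom is covered.
    """
    adj = molecule.neighbors()
    bodies: list[Body] = []
    covered: set[int] = set()
    next_id = 0
    for atom in molecule.atoms:
        s = atom.serial
        if len(adj[s]) >= 2:
            members = frozenset({s} | adj[s])
            bodies.append(Body(next_id, members, "atom_hub", hub=s))
            covered |= members
            next_id += 1
    for atom in molecule.atoms:
        s = atom.serial
        if s in covered:
            continue
        if len(adj[s]) == 0:
            bodies.append(Body(next_id, frozenset({s}), "atom_hub", hub=s))
            covered.add(s)
            next_id += 1
        else:  # degree-1 atom whose sole neighbor is also degree-1
            other = next(iter(adj[s]))
            if other in covered:
                continue
            members = frozenset({s, other})
            bodies.append(Body(next_id, members, "atom_hub", hub=min(s, other)))
            covered |= members
            next_id += 1
    return bodies


def _resolve_body(serial: int, hub_of: dict[int, int],
                  containing: dict[int, list[int]]) -> int:
    """Body anchoring an atom: its own hub body if it has one, else the
    unique body containing it."""
    if serial in hub_of:
        return hub_of[serial]
    owners = containing.get(serial, [])
    if not owners:
        raise ModelingError(f"atom {serial} belongs to no body")
    return owners[0]


def assign_connections(bodies: list[Body], network: InteractionNetwork,
                       options: ModelingOptions | None = None
                       ) -> BodyBarHingeModel:
    """Model every interaction as a connection between two bodies.

    A covalent bond between two hub atoms becomes a joint between their hub
    bodies with that bond as the hinge axis (or b bars, per options).
    Non-covalent interactions attach to the body hubbed at each participant
    atom, falling back to the atom's containing body.  Interactions whose
    endpoints resolve to the same body constrain nothing and are logged.
    """
    options = options or ModelingOptions()
    hub_of = {b.hub: b.id for b in bodies if b.hub is not None}
    containing: dict[int, list[int]] = {}
    for b in bodies:
        for s in sorted(b.atoms):
            containing.setdefault(s, []).append(b.id)

    connections: list[Connection] = []
    internal: list[tuple] = []
    covalent_kinds = {"covalent_single", "covalent_double", "peptide"}
    next_id = 0
    for inter in network.interactions:
        sa, sb = inter.atoms
        if inter.kind in covalent_kinds:
            if sa in hub_of and sb in hub_of:
                u, v = hub_of[sa], hub_of[sb]
            else:
                internal.append(inter.id)  # bond buried inside one body
                continue
        else:
            u = _resolve_body(sa, hub_of, containing)
            v = _resolve_body(sb, hub_of, containing)
        if u == v:
            internal.append(inter.id)
            continue
        model = options.model_for(inter.kind)
        axis = (sa, sb) if model == HINGE else None
        connections.append(Connection(
            id=next_id, bodies=(min(u, v), max(u, v)),
            model=model, source=inter.id, axis=axis,
        ))
        next_id += 1
    return BodyBarHingeModel(bodies, connections, network.molecule,
                             network, internal)


def build_model(molecule: Molecule, network: InteractionNetwork,
                options: ModelingOptions | None = None) -> BodyBarHingeModel:
    """Convenience: build_bodies + assign_connections."""
    return assign_connections(build_bodies(molecule), network, options)


def to_multigraph(model: BodyBarHingeModel) -> Multigraph:
    """One vertex per body; 5 parallel edges per hinge, b per bar connection."""
    vertices = [b.id for b in model.bodies]
    edges: list[tuple[int, int, int]] = []
    for conn in model.connections:
        u, v = conn.bodies
        edges.extend((u, v, conn.id) for _ in range(conn.edge_count))
    return Multigraph(vertices, edges)


# ---------------------------------------------------------------------------
# Edge-list text interchange
# ---------------------------------------------------------------------------

def multigraph_to_edge_list(graph: Multigraph) -> str:
    """Plain-text edge list: header with vertices, one line per edge."""
    lines = ["# vertices: " + " ".join(str(v) for v in graph.vertices),
             "# u\tv\tconnection_id"]
    lines += [f"{u}\t{v}\t{t}" for u, v, t in graph.edges]
    return "\n".join(lines) + "\n"


def multigraph_from_edge_list(text: str) -> Multigraph:
    vertices: list[int] = []
    edges: list[tuple[int, int, int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# vertices:"):
            vertices = [int(tok) for tok in line.split(":", 1)[1].split()]
        elif line.startswith("#"):
            continue
        else:
            u, v, t = (int(tok) for tok in line.split("\t"))
            edges.append((u, v, t))
    if not vertices:
        vertices = sorted({u for u, _v, _t in edges} | {v for _u, v, _t in edges})
    return Multigraph(vertices, edges)
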