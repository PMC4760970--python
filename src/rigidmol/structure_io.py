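"""Structure input, curation, and covalent bond perception.

Reads PDB-format coordinate files, performs reproducible curation
(chain/solvent/ligand selection, alternate-location resolution) with a
replayable log, perceives the covalent bond network from bundled residue
templates (coordinate-free for standard residues, distance-based fallback
otherwise), and builds deterministic ideal-geometry fixture molecules for
testing and demonstration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._data import (
    COVALENT_RADII,
    DEFAULT_COVALENT_RADIUS,
    ELEMENTS,
    RESIDUE_BONDS,
    RESIDUE_DOUBLE_BONDS,
    STANDARD_AMINO_ACIDS,
    STANDARD_NUCLEOTIDES,
    WATER_RESNAMES,
)

__all__ = [
    "Atom",
    "CovalentBond",
    "Molecule",
    "CurationConfig",
    "CurationLog",
    "PDBError",
    "CurationError",
    "FixtureError",
    "parse_pdb",
    "curate",
    "replay_curation",
    "perceive_covalent_bonds",
    "detect_gaps",
    "make_fixture",
    "FIXTURE_NAMES",
    "molecule_to_json",
    "molecule_from_json",
]


class PDBError(ValueError):
    """Raised for unreadable or coordinate-free PDB input."""


class CurationError(ValueError):
    """Raised when curation produces an invalid (e.g. empty) molecule."""


class FixtureError(ValueError):
    """Raised for unknown fixture names or parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom record.

    Residue numbering is kept exactly as deposited (PDB convention);
    coordinates are in Å, b_factor in Å².
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.element.upper() not in ELEMENTS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass(frozen=True)
class CovalentBond:
    """An unordered covalent bond between two atom serials.

    order is one of single / double / peptide / disulfide.
    """

    a: int
    b: int
    order: str = "single"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("bond endpoints must be distinct")
        if self.a > self.b:  # canonical orientation for set semantics
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)
        if self.order not in {"single", "double", "peptide", "disulfide"}:
            raise ValueError(f"unknown bond order {self.order!r}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b)


class Molecule:
    """Atoms plus a covalent bond list, with provenance.

    Atom serials are unique; bonds reference existing serials.  Atom order
    is file order (or construction order for fixtures) and is preserved by
    every operation in this package.
    """

    def __init__(self, atoms, bonds=(), provenance=None):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[CovalentBond] = list(bonds)
        self.provenance: dict = dict(provenance or {})
        self._by_serial = {a.serial: a for a in self.atoms}
        if len(self._by_serial) != len(self.atoms):
            raise ValueError("duplicate atom serials")
        seen = set()
        for b in self.bonds:
            if b.a not in self._by_serial or b.b not in self._by_serial:
                raise ValueError(f"bond {b.pair} references missing atoms")
            if b.pair in seen:
                raise ValueError(f"duplicate bond {b.pair}")
            seen.add(b.pair)

    # -- access helpers ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, serial: int) -> Atom:
        return self._by_serial[serial]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def neighbors(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {a.serial: set() for a in self.atoms}
        for b in self.bonds:
            adj[b.a].add(b.b)
            adj[b.b].add(b.a)
        return adj

    def residues(self):
        """Yield (residue_key, residue_name, [atoms]) in file order."""
        order: list[tuple] = []
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            key = a.residue_key
            if key not in groups:
                groups[key] = []
                order.append((key, a.residue_name))
            groups[key].append(a)
        for key, name in order:
            yield key, name, groups[key]

    def with_atoms(self, atoms, provenance=None) -> "Molecule":
        keep = {a.serial for a in atoms}
        bonds = [b for b in self.bonds if b.a in keep and b.b in keep]
        return Molecule(atoms, bonds, provenance or self.provenance)

    def with_bonds(self, bonds) -> "Molecule":
        return Molecule(self.atoms, bonds, self.provenance)


@dataclass
class CurationConfig:
    """Options controlling reproducible curation."""

    chains: tuple[str, ...] = ()          # empty = keep all
    prune_water: bool = False
    prune_ligands: bool = False
    keep_nucleic: bool = True
    model_index: int = 1
    # alt_loc policy is fixed: highest occupancy, ties alphabetically first

    def __post_init__(self) -> None:
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")
        self.chains = tuple(self.chains)


@dataclass
class CurationLog:
    """Ordered record of curation actions; replayable and serializable."""

    actions: list[dict] = field(default_factory=list)

    def record(self, action: str, **params) -> None:
        self.actions.append(
            {"seq": len(self.actions), "action": action, "params": params}
        )

    def to_json(self) -> str:
        return json.dumps({"curation_log": self.actions}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CurationLog":
        return cls(actions=json.loads(text)["curation_log"])


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _conect_pairs(text: str) -> list[tuple[int, int]]:
    """Extract bonded serial pairs from CONECT records (fixed columns)."""
    pairs = []
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = []
        for start in (6, 11, 16, 21, 26):
            tok = line[start:start + 5].strip()
            if tok:
                try:
                    fields.append(int(tok))
                except ValueError:
                    pass
        for other in fields[1:]:
            if fields and other != fields[0]:
                pairs.append((min(fields[0], other), max(fields[0], other)))
    return sorted(set(pairs))


def parse_pdb(text: str, model_index: int = 1) -> Molecule:
    """Parse PDB-format text into a Molecule (no bonds perceived yet).

    MODEL blocks are resolved to ``model_index`` (1-based).  Alternate
    locations are retained raw and resolved later by :func:`curate`.
    CONECT records are kept in provenance and merged during bond perception.
    """
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise PDBError("no ATOM/HETATM coordinate records found")
    n_models = len(structure)
    if not 1 <= model_index <= n_models:
        available = ", ".join(str(m.num) for m in structure)
        raise PDBError(
            f"model {model_index} not present; available models: {available}"
        )
    model = structure[model_index - 1]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                altloc = at.altloc if at.altloc not in ("\x00", "") else ""
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name.upper(),
                    alt_loc=altloc,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                    is_hetatm=res.het_flag == "H",
                ))
    if not atoms:
        raise PDBError("no ATOM/HETATM coordinate records found")
    prov = {
        "source": structure.name or "pdb",
        "model_index": model_index,
        "conect": _conect_pairs(text),
    }
    return Molecule(atoms, (), prov)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _is_water(a: Atom) -> bool:
    return a.residue_name in WATER_RESNAMES


def _is_nucleic(a: Atom) -> bool:
    return a.residue_name in STANDARD_NUCLEOTIDES


def _apply_keep_chains(atoms, chains):
    keep = set(chains)
    return [a for a in atoms if a.chain_id in keep]


def _apply_prune_water(atoms):
    return [a for a in atoms if not _is_water(a)]


def _apply_prune_ligands(atoms):
    return [a for a in atoms if not (a.is_hetatm and not _is_water(a))]


def _apply_prune_nucleic(atoms):
    return [a for a in atoms if not _is_nucleic(a)]


def _apply_resolve_altloc(atoms):
    """Keep one atom per (residue, name): highest occupancy, tie -> first
    alt_loc alphabetically; the survivor's alt_loc field is cleared."""
    best: dict[tuple, Atom] = {}
    for a in atoms:
        key = (a.residue_key, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
        elif (a.occupancy, _altloc_rank(cur.alt_loc)) > (
                cur.occupancy, _altloc_rank(a.alt_loc)):
            best[key] = a
    survivors = set(id(a) for a in best.values())
    return [replace(a, alt_loc="") if a.alt_loc else a
            for a in atoms if id(a) in survivors]


def _altloc_rank(alt: str) -> int:
    # higher rank = less preferred; '' sorts before 'A'
    return 0 if alt == "" else ord(alt[0])


_ACTIONS = {
    "keep_chains": lambda atoms, p: _apply_keep_chains(atoms, p["chains"]),
    "prune_water": lambda atoms, p: _apply_prune_water(atoms),
    "prune_ligands": lambda atoms, p: _apply_prune_ligands(atoms),
    "prune_nucleic": lambda atoms, p: _apply_prune_nucleic(atoms),
    "resolve_altloc": lambda atoms, p: _apply_resolve_altloc(atoms),
}


def curate(molecule: Molecule, config: CurationConfig):
    """Apply in-silico surgery per ``config``; returns (Molecule, CurationLog).

    Pure function: the input molecule is never mutated, atom order is
    preserved, and replaying the returned log on the same input reproduces
    the identical curated molecule.
    """
    present = set(molecule.chains)
    missing = [c for c in config.chains if c not in present]
    if missing:
        raise CurationError(
            f"requested chains not in molecule: {sorted(missing)}; "
            f"present: {sorted(present)}"
        )

    log = CurationLog()
    atoms = list(molecule.atoms)

    def run(action: str, **params) -> None:
        nonlocal atoms
        before = len(atoms)
        atoms = _ACTIONS[action](atoms, params)
        log.record(action, removed=before - len(atoms), **params)

    if config.chains:
        run("keep_chains", chains=list(config.chains))
    if config.prune_water:
        run("prune_water")
    if config.prune_ligands:
        run("prune_ligands")
    if not config.keep_nucleic:
        run("prune_nucleic")
    run("resolve_altloc")

    if not atoms:
        raise CurationError("curation removed every atom")
    return molecule.with_atoms(atoms), log


def replay_curation(molecule: Molecule, log: CurationLog) -> Molecule:
    """Re-apply a recorded curation log; yields the identical curated result."""
    atoms = list(molecule.atoms)
    for entry in log.actions:
        params = {k: v for k, v in entry["params"].items() if k != "removed"}
        atoms = _ACTIONS[entry["action"]](atoms, params)
    if not atoms:
        raise CurationError("curation removed every atom")
    return molecule.with_atoms(atoms)


# ---------------------------------------------------------------------------
# Covalent bond perception
# ---------------------------------------------------------------------------

def _hydrogen_parent(h_name: str, heavy_names: list[str]) -> str | None:
    """Coordinate-free parent assignment for a hydrogen by PDB name.

    HB2 -> CB, HG12 -> CG1, HD21 -> ND2, ...; bare H/H1/H2/H3 -> backbone N.
    """
    name = h_name
    if name and name[0].isdigit():      # old-style 1HB2 -> HB2
        name = name[1:] + name[0]
    if name in {"H", "H1", "H2", "H3", "HN", "HT1", "HT2", "HT3"}:
        return "N" if "N" in heavy_names else None
    stem = name[1:]
    candidates = [stem]
    if stem and stem[-1].isdigit():
        candidates.append(stem[:-1])
    for cand in candidates:
        for el in ("C", "N", "O", "S"):
            if el + cand in heavy_names:
                return el + cand
    return None


def _distance_bonds(atoms: list[Atom], tol: float = 0.4) -> set[tuple[int, int]]:
    """All-pairs covalent perception: d <= r_cov(a) + r_cov(b) + tol."""
    if len(atoms) < 2:
        return set()
    from scipy.spatial import cKDTree

    coords = np.array([a.coords for a in atoms])
    radii = np.array([
        COVALENT_RADII.get(a.element.upper(), DEFAULT_COVALENT_RADIUS)
        for a in atoms
    ])
    rmax = 2 * radii.max() + tol
    tree = cKDTree(coords)
    out: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(rmax):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= radii[i] + radii[j] + tol and d > 0.1:
            si, sj = atoms[i].serial, atoms[j].serial
            out.add((min(si, sj), max(si, sj)))
    return out


def perceive_covalent_bonds(molecule: Molecule) -> Molecule:
    """Return a copy of ``molecule`` with the covalent bond list filled in.

    Template residues (standard amino acids, water) get bonds from the
    bundled table — coordinate-free, so small coordinate noise never changes
    them.  Hydrogens in template residues attach to their parent heavy atom
    by PDB-name convention.  Non-template residues fall back to a distance
    rule on summed covalent radii (+0.4 Å).  Consecutive amino acids in a
    chain are joined C->N (order=peptide); consecutive nucleotides O3'->P.
    CONECT pairs from provenance are merged in.
    """
    bonds: dict[tuple[int, int], str] = {}

    def add(sa: int, sb: int, order: str = "single") -> None:
        key = (min(sa, sb), max(sa, sb))
        # peptide/double annotations win over plain single (CONECT overlap)
        if key not in bonds or bonds[key] == "single":
            bonds[key] = order

    fallback_atoms: list[Atom] = []
    residue_list = list(molecule.residues())
    for _key, resname, atoms in residue_list:
        template = RESIDUE_BONDS.get(resname)
        if template is None:
            fallback_atoms.extend(atoms)
            continue
        by_name: dict[str, Atom] = {}
        for a in atoms:
            by_name.setdefault(a.name, a)
        doubles = set(RESIDUE_DOUBLE_BONDS.get(resname, ()))
        for na, nb in template:
            if na in by_name and nb in by_name:
                order = ("double" if (na, nb) in doubles or (nb, na) in doubles
                         else "single")
                add(by_name[na].serial, by_name[nb].serial, order)
        heavy_names = [a.name for a in atoms if a.element.upper() != "H"]
        for a in atoms:
            if a.element.upper() != "H":
                continue
            parent = _hydrogen_parent(a.name, heavy_names)
            if parent is not None and parent in by_name:
                add(a.serial, by_name[parent].serial)

    for pair in _distance_bonds(fallback_atoms):
        add(*pair)

    # inter-residue backbone links between consecutive residues of a chain
    for (k1, n1, a1), (k2, n2, a2) in zip(residue_list, residue_list[1:]):
        if k1[0] != k2[0]:
            continue
        seq_ok = (k2[1] - k1[1] == 1) or (k2[1] == k1[1] and k1[2] != k2[2])
        if not seq_ok:
            continue
        d1 = {a.name: a for a in a1}
        d2 = {a.name: a for a in a2}
        if (n1 in STANDARD_AMINO_ACIDS and n2 in STANDARD_AMINO_ACIDS
                and "C" in d1 and "N" in d2):
            add(d1["C"].serial, d2["N"].serial, "peptide")
        elif (n1 in STANDARD_NUCLEOTIDES and n2 in STANDARD_NUCLEOTIDES
                and "O3'" in d1 and "P" in d2):
            add(d1["O3'"].serial, d2["P"].serial)

    for sa, sb in molecule.provenance.get("conect", ()):
        if sa in molecule._by_serial and sb in molecule._by_serial:
            add(sa, sb)

    bond_list = [CovalentBond(a, b, order)
                 for (a, b), order in sorted(bonds.items())]
    return molecule.with_bonds(bond_list)


def detect_gaps(molecule: Molecule) -> list[tuple[str, int]]:
    """Report chain breaks: (chain_id, residue_seq before the gap).

    A gap is a pair of consecutive observed amino-acid residues whose
    residue_seq differ by more than 1; insertion codes count as continuity.
    """
    gaps: list[tuple[str, int]] = []
    prev: dict[str, int] = {}
    seen: set[tuple[str, int]] = set()
    for key, resname, _atoms in molecule.residues():
        if resname not in STANDARD_AMINO_ACIDS:
            continue
        chain, seq, _icode = key
        if (chain, seq) in seen:
            continue
        seen.add((chain, seq))
        if chain in prev and seq - prev[chain] > 1:
            gaps.append((chain, prev[chain]))
        prev[chain] = seq
    return gaps


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def molecule_to_json(molecule: Molecule) -> str:
    """Stable JSON serialization (byte-identical for identical molecules)."""
    doc = {
        "provenance": {k: v for k, v in sorted(molecule.provenance.items())
                       if k != "conect"},
        "atoms": [
            {
                "serial": a.serial, "name": a.name, "element": a.element,
                "alt_loc": a.alt_loc, "residue_name": a.residue_name,
                "chain_id": a.chain_id, "residue_seq": a.residue_seq,
                "insertion_code": a.insertion_code,
                "coords": [round(c, 6) for c in a.coords],
                "occupancy": round(a.occupancy, 4),
                "b_factor": round(a.b_factor, 4),
                "is_hetatm": a.is_hetatm,
            }
            for a in molecule.atoms
        ],
        "bonds": [
            {"a": b.a, "b": b.b, "order": b.order} for b in molecule.bonds
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def molecule_from_json(text: str) -> Molecule:
    doc = json.loads(text)
    atoms = [
        Atom(
            serial=d["serial"], name=d["name"], element=d["element"],
            alt_loc=d["alt_loc"], residue_name=d["residue_name"],
            chain_id=d["chain_id"], residue_seq=d["residue_seq"],
            insertion_code=d["insertion_code"], coords=tuple(d["coords"]),
            occupancy=d["occupancy"], b_factor=d["b_factor"],
            is_hetatm=d["is_hetatm"],
        )
        for d in doc["atoms"]
    ]
    bonds = [CovalentBond(d["a"], d["b"], d["order"]) for d in doc["bonds"]]
    return Molecule(atoms, bonds, doc.get("provenance", {}))


# ---------------------------------------------------------------------------
# Fixture molecules (deterministic ideal geometry)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("water", "ethane", "ethylene", "dipeptide", "toy_helix")

# ideal internal coordinates (Engh & Huber-style values)
_N_CA, _CA_C, _C_N = 1.458, 1.525, 1.329
_C_O, _N_H, _C_H = 1.231, 1.010, 1.090
_CA_CB = 1.521
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O, _ANG_C_N_H = 120.8, 119.0


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position d bonded to c with the given internal coords."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _round3(v) -> tuple[float, float, float]:
    return (round(float(v[0]), 3), round(float(v[1]), 3), round(float(v[2]), 3))


def _mk_atoms(spec, chain="A", het=False) -> list[Atom]:
    """spec: iterable of (name, element, resname, resseq, xyz)."""
    atoms = []
    for i, (name, element, resname, resseq, xyz) in enumerate(spec, start=1):
        atoms.append(Atom(
            serial=i, name=name, element=element, alt_loc="",
            residue_name=resname, chain_id=chain, residue_seq=resseq,
            insertion_code="", coords=_round3(xyz), occupancy=1.0,
            b_factor=0.0, is_hetatm=het,
        ))
    return atoms


def _fixture_water() -> list:
    th = math.radians(104.5)
    r = 0.9572
    return [
        ("O", "O", "HOH", 1, (0.0, 0.0, 0.0)),
        ("H1", "H", "HOH", 1, (r, 0.0, 0.0)),
        ("H2", "H", "HOH", 1, (r * math.cos(th), r * math.sin(th), 0.0)),
    ]


def _tetra_dirs(phase_deg: float):
    """Three unit vectors at 109.47° from +x, at the given azimuthal phase."""
    ct = -1.0 / 3.0
    st = math.sqrt(1 - ct * ct)
    out = []
    for k in range(3):
        phi = math.radians(phase_deg + 120.0 * k)
        out.append(np.array([ct, st * math.cos(phi), st * math.sin(phi)]))
    return out


def _fixture_ethane() -> list:
    c1 = np.zeros(3)
    c2 = np.array([1.54, 0.0, 0.0])
    spec = [("C1", "C", "ETH", 1, c1), ("C2", "C", "ETH", 1, c2)]
    for k, d in enumerate(_tetra_dirs(0.0), 1):       # dirs away from C2
        spec.append((f"H1{k}", "H", "ETH", 1, c1 - 1.09 * d * np.array([-1, 1, 1])))
    for k, d in enumerate(_tetra_dirs(60.0), 1):      # staggered
        spec.append((f"H2{k}", "H", "ETH", 1, c2 + 1.09 * d * np.array([1, 1, 1])))
    return spec


def _fixture_ethylene() -> list:
    c1 = np.zeros(3)
    c2 = np.array([1.33, 0.0, 0.0])
    s, c = math.sin(math.radians(60)), math.cos(math.radians(60))
    return [
        ("C1", "C", "ETL", 1, c1),
        ("C2", "C", "ETL", 1, c2),
        ("H11", "H", "ETL", 1, c1 + 1.085 * np.array([-c, s, 0.0])),
        ("H12", "H", "ETL", 1, c1 + 1.085 * np.array([-c, -s, 0.0])),
        ("H21", "H", "ETL", 1, c2 + 1.085 * np.array([c, s, 0.0])),
        ("H22", "H", "ETL", 1, c2 + 1.085 * np.array([c, -s, 0.0])),
    ]


def _build_polyala(n_res: int, phi: float, psi: float) -> list:
    """Ideal poly-alanine backbone with amide hydrogens, CB and methyl H."""
    spec: list = []
    N = np.zeros(3)
    CA = N + np.array([_N_CA, 0.0, 0.0])
    th = math.radians(_ANG_N_CA_C)
    C = CA + _CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    prevN = prevC = prevCA = prevO = None
    for i in range(1, n_res + 1):
        if i > 1:
            N = _place(prevN, prevCA, prevC, _C_N, _ANG_CA_C_N, psi)
            CA = _place(prevCA, prevC, N, _N_CA, _ANG_C_N_CA, 180.0)
            C = _place(prevC, N, CA, _CA_C, _ANG_N_CA_C, phi)
        O = _place(N, CA, C, _C_O, _ANG_CA_C_O, psi + 180.0)
        if i > 1:
            H = _place(prevO, prevC, N, _N_H, _ANG_C_N_H, 180.0)
        else:
            H = _place(C, CA, N, _N_H, 109.5, 180.0)
        CB = _place(C, N, CA, _CA_CB, 110.4, phi + 122.5)
        HA = _place(C, N, CA, _C_H, 108.0, phi - 118.5)
        spec.append(("N", "N", "ALA", i, N))
        spec.append(("CA", "C", "ALA", i, CA))
        spec.append(("C", "C", "ALA", i, C))
        spec.append(("O", "O", "ALA", i, O))
        spec.append(("CB", "C", "ALA", i, CB))
        spec.append(("H", "H", "ALA", i, H))
        spec.append(("HA", "H", "ALA", i, HA))
        for k, tor in enumerate((60.0, 180.0, 300.0), 1):
            spec.append((f"HB{k}", "H", "ALA", i,
                         _place(N, CA, CB, _C_H, 109.5, tor)))
        prevN, prevC, prevCA, prevO = N, C, CA, O
    return spec


def make_fixture(name: str, seed: int = 0, **params) -> Molecule:
    """Build a deterministic ideal-geometry fixture molecule.

    Names: water, ethane, ethylene, dipeptide, toy_helix(n_res).  Hydrogens
    are always present.  toy_helix places alanine-like residues on an ideal
    helix (φ=−70°, ψ=−46°, a slightly tightened α-helix) so that every
    i→i+4 backbone amide pair — and no other pair — has hydrogen-bond
    geometry.  Identical (name, params, seed) give identical
    output; the seed is accepted for API uniformity and does not perturb the
    ideal geometry.
    """
    if name == "water":
        spec = _fixture_water()
        het = True
    elif name == "ethane":
        spec = _fixture_ethane()
        het = True
    elif name == "ethylene":
        spec = _fixture_ethylene()
        het = True
    elif name == "dipeptide":
        spec = _build_polyala(2, phi=-140.0, psi=135.0)
        het = False
    elif name == "toy_helix":
        n_res = int(params.pop("n_res", 8))
        if n_res < 1:
            raise FixtureError("toy_helix requires n_res >= 1")
        spec = _build_polyala(n_res, phi=-70.0, psi=-46.0)
        het = False
    else:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if params:
        raise FixtureError(f"unknown fixture parameters: {sorted(params)}")
    mol = Molecule(_mk_atoms(spec, het=het),
                   provenance={"source": f"fixture:{name}", "seed": seed})
    mol = perceive_covalent_bonds(mol)
    if name == "ethylene":
        bonds = [CovalentBond(b.a, b.b, "double")
                 if {mol.atom(b.a).name, mol.atom(b.b).name} == {"C1", "C2"}
                 else b
                 for b in mol.bonds]
        mol = mol.with_bonds(bonds)
    return mol
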