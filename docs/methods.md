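# Methods

This note documents the model behind `rigidmol`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic fixtures do and do not establish about real structures.

## Rigidity model

A molecule is treated as a mechanical framework of rigid bodies connected
by constraints, and its generic rigidity is decided combinatorially.

**Bodies.** Every atom with covalent degree ≥ 2 yields an *atom-hub*
body containing the atom and all its covalent neighbors. Two adjacent hub
bodies therefore overlap on the two atoms of the bond between them — that
bond is the candidate hinge axis. Degree-≤1 atoms live only inside their
neighbor's body; isolated atoms (and bonded pairs of two degree-1 atoms)
become their own trivial bodies so every atom is covered. Hub bodies are
exact rigid units under fixed bond lengths and angles, which is the
standard local-geometry assumption of this class of models.

**Joints.** Each interaction becomes one connection between two bodies:

| interaction        | default model | multigraph edges |
|--------------------|---------------|------------------|
| rotatable covalent | hinge         | 5                |
| peptide bond       | 6 bars        | 6                |
| double bond        | 6 bars        | 6                |
| disulfide          | hinge         | 5                |
| hydrogen bond      | hinge         | 5                |
| hydrophobic        | 3 bars        | 3                |

A hinge removes 5 of the 6 relative degrees of freedom between two bodies
in 3D (one torsion survives); locking a non-rotatable bond means 6 bars.
Hydrophobic contacts restrict relative sliding without fixing relative
orientation, hence the conventional 3 bars. Any kind can be remapped to
`hinge` or to `b ∈ [1, 6]` bars through `ModelingOptions`; values outside
[1, 6] are rejected. An interaction whose endpoints resolve to the same
body constrains nothing and is logged rather than silently dropped. For a
hydrogen bond the mechanical axis is the H···A contact (the donor–H bond
is already covalent).

**Pebble game.** The multigraph (vertex per body, 5 edges per hinge, *b*
per bar joint) feeds the (k,l)-pebble game with k = l = 6. An edge set is
(6,6)-sparse when every vertex subset S with |S| ≥ 2 spans at most
6|S| − 6 edges; the game maintains 6 pebbles per vertex and a directed
graph of accepted edges, accepting an edge exactly when 7 pebbles can be
gathered on its endpoints. Accepted edges form a maximum independent set
(matroid rank), rejected ones are redundant, and Σ free pebbles =
6|V| − rank is the total free DoF, ≥ 6 for any non-empty connected
framework (the trivial rigid motions).

*Determinism and order.* Edges are inserted in a fixed order (connection
id, then endpoints), so the identity of the redundant edges is
reproducible run to run. Only rank, free pebbles and components are
order-invariant — which specific edges get called redundant is not a
matroid invariant, and downstream code never relies on it.

*Components.* For l = k, rigidity composes through a shared body: if S₁
and S₂ are rigid and share a vertex, i(S₁∪S₂) ≥ 6|S₁∪S₂| − 6 and the
union is rigid. The "rigid pair" relation (at most 6 pebbles can be
gathered onto {u, v}) is therefore transitive, and components are its
equivalence classes, computed after the game by pebble-gathering probes.
Gathering only redistributes pebbles and reverses accepted edges — both
leave the matroid state intact — so probes need no rollback. The engine
is parameterized over (k, l) and its rank/redundancy answers are exact
for any valid pair (property-tested against the exhaustive oracle); the
component decomposition is only defined here for l = k, the body-framework
case, and is `None` otherwise. A consequence worth stating: for l = k,
maximal components are vertex-disjoint; the familiar cluster *overlap*
appears only at the atom level, where two clusters may share exactly the
two atoms of a hinge axis.

*Oracles.* `oracle_rank` / `oracle_components` implement the definitions
directly — greedy augmentation with exhaustive sparsity verification over
all vertex subsets, and enumeration of all maximal tight sets — for
graphs with |V| ≤ 8, |E| ≤ 48. They share no code path with the game.

**Clusters.** Each component maps to the union of its bodies' atoms;
bodies outside every component become trivial clusters (including
isolated-atom bodies, e.g. zero-degree HETATM atoms — reported rather
than dropped, so atom coverage is total). Clusters are labeled 1..n by
decreasing size, ties broken by smallest contained atom serial, which
makes labels, serializations, and colors deterministic. Connections
joining bodies of different clusters are inherited as the decomposition's
flexible joints.

## Interaction detection

**Hydrogen bonds.** Donors are N/O with a covalently attached H;
acceptors are N/O. Gates: donor–acceptor distance ≤ 3.5 Å and D–H···A
angle ≥ 90°. Donor–acceptor pairs within 3 covalent bonds are excluded —
without this, peptide-adjacent backbone N/O pairs (2.3–2.9 Å apart along
the chain) would masquerade as hydrogen bonds. Each passing
(donor, H, acceptor) triple is scored with an explicit Mayo-style form

    E = D0 · [5 (R0/d)^12 − 6 (R0/d)^10] · sin²(θ − 90°)

with d the D–A distance, θ the D–H···A angle (the angular factor equals
cos²(180° − θ) and vanishes exactly at the gate), D0 = 8 kcal/mol,
R0 = 2.75 Å; the value is clamped at ≤ 0 so an admissible geometry never
scores repulsive. The global minimum −D0 sits at d = R0, θ = 180°. All
constants live in `InteractionParams` so the form can be re-parameterized;
cluster decompositions are known to be sensitive to hydrogen-bond
placement, which is exactly why the formula is explicit and swappable
rather than implied. Hydrogen placement itself is out of scope: structures
must arrive protonated, and detection raises (never returns silently
empty) on a hydrogen-free molecule.

**Energy cutoff.** `prune_by_cutoff` removes hydrogen bonds with energy
above (weaker than) the cutoff, default −1.0 kcal/mol — the primary
tunable of the analysis. Pruning is monotone in the cutoff and touches no
other interaction kind.

**Hydrophobic contacts.** Carbon/sulfur pairs in different residues with
d ≤ r_vdw(a) + r_vdw(b) + 0.25 Å, subject to the same 3-bond exclusion;
only the closest pair per residue pair is kept, so one packed interface
contributes one 3-bar joint instead of inflating the bar count with every
grazing atom pair. Hydrophobics are gated geometrically only — they carry
no energy and are unaffected by the cutoff.

**Disulfides.** SG–SG pairs of distinct cysteines within 2.5 Å, modeled
as hinges (a rotatable S–S single bond).

## Structure input and curation

PDB text is parsed with gemmi; MODEL blocks resolve to a requested model
(1-based, with an error naming the available models), CONECT pairs are
scanned from the raw records and merged into bond perception. Curation
(chain selection, water/ligand/nucleic pruning, alternate-location
resolution: highest occupancy, ties to the alphabetically first altloc)
is a pure function that emits an ordered, JSON-serializable log; replaying
the log on the same input reproduces the byte-identical curated molecule.
Gap detection reports consecutive observed amino acids whose numbering
jumps by more than 1 (insertion codes count as continuity).

Covalent bonds come from bundled heavy-atom templates for the 20 standard
amino acids plus water, with hydrogens attached by a coordinate-free
name-based parent rule (HB2 → CB, HG12 → CG1, bare H/H1–H3 → backbone N);
template-derived bonds are untouched by coordinate noise, by construction.
Residues without a template (ligands, nucleotides) fall back to a distance
rule, d ≤ r_cov(a) + r_cov(b) + 0.4 Å, a standard perception tolerance.
Consecutive amino acids are joined C→N (`peptide` order), consecutive
nucleotides O3′→P. Residue numbering is kept exactly as deposited.

## Derivative analyses

**Dilution.** Hydrogen bonds are removed one at a time; after each
removal the decomposition is recomputed from scratch on the remaining
network, so snapshots are exactly what an independent analysis of that
network would give, and each snapshot refines its predecessor (removing
constraints never creates rigidity). Orders: `weakest_first` (default —
energy closest to zero removed first), `strongest_first`, and `depth`
(shallowest first). The energy direction is genuinely ambiguous in the
unfolding literature — "increasing energy" reads opposite ways for
negative energies — so both directions are first-class options rather
than a guessed intent. The per-step, per-residue cluster-label table
(each residue tracked by its Cα) is the data behind a 1D dilution plot.

**Bond depth.** Distance from the bond midpoint to the nearest facet of
the convex hull of all atoms (0 on or outside the hull) — deterministic
and rigid-motion-invariant; the hull needs ≥ 4 non-coplanar atoms.

**Alanine scanning.** A mutation removes every hydrogen bond and
hydrophobic contact with a participant in the residue's side chain beyond
Cβ (name-based: anything outside backbone + Cβ + their hydrogens);
covalent topology is untouched. Including hydrophobics is a deliberate
extension of a narrower hydrogen-bond-only reading: alanine substitution
physically removes side-chain packing too. GLY/ALA/PRO are skipped with a
warning result. The destabilization score is declared, not canonical:
wild-type largest-cluster size minus mutant largest-cluster size, ties by
increase in cluster count, then input order (stable sort).

**Redundancy.** A bond is *redundant* iff removing it leaves the rigid
cluster decomposition unchanged, *critical* otherwise. The comparison is
definitional — remove, recompute from scratch, compare — over both the
cluster atom sets and the framework's total free DoF. The DoF term is
essential: a lone hinge joining two otherwise-independent clusters leaves
the cluster list unchanged when removed, yet all five of its edges are
independent constraints and the structure loosens by five DoF; calling it
redundant would invert the intended meaning (redundancy as
over-constraint, a stronger stability indicator than rigidity). With the
DoF term the label is equivalent to "every multigraph edge of the bond is
matroid-redundant". No pebble-level fast path is used — the definitional
route is fast at this package's scale and cannot disagree with itself.

**Consistent coloring.** Size coloring assigns palette colors to clusters
of ≥ 5 atoms (configurable threshold; only dominant clusters deserve
distinct colors) in label order, cycling with a warning flag if the
palette runs out. Dilution coloring colors step 0 by size and thereafter
lets each parent's largest child (ties to smallest atom serial) inherit
the parent's color; other above-threshold children draw colors never used
before in the series, so no color ever refers to two coexisting clusters.
Parenthood is decided by maximal atom overlap, and a non-refining series
is rejected with the violating step named. Cross-decomposition coloring
runs Gale–Shapley stable matching with preferences by raw shared-atom
count (ties by label; zero overlap mutually unacceptable; Jaccard was
considered and rejected as an extra normalization with no testable
benefit here). The first argument proposes — stable matchings are
side-dependent, so fixing the proposer is what makes the output
deterministic. Matched pairs share a color; unmatched dominant clusters
get fresh ones.

## Synthetic fixtures

`make_fixture` builds deterministic ideal-geometry molecules: water,
staggered ethane, planar ethylene (C=C marked double), a dipeptide
(φ = −140°, ψ = 135°), and `toy_helix(n_res)` — poly-alanine on an ideal
helix with φ = −70°, ψ = −46°, a slightly tightened α-helix chosen so
that every i→i+4 backbone amide pair passes the hydrogen-bond gates
(N···O ≈ 2.71 Å, D–H···A ≈ 140°) while every i→i+3 and i→i+5 pair fails
them with a clear margin. At canonical α-helix torsions the i→i+3
contacts sit right at the default gates and detection counts would be
fragile; the tightened torsions make the fixture's contract (exactly the
i+4 ladder) robust. Backbones are grown by natural-extension (NeRF)
internal-coordinate placement with Engh–Huber-style bond lengths and
angles; coordinates are rounded to 3 decimals so serializations are
byte-stable across platforms. The `seed` argument is accepted for API
uniformity but the geometry is ideal and seed-independent.

What fixtures do *not* show: real structures have missing atoms,
alternate conformations, non-ideal geometry, waters and ligands, and
hydrogen-bond networks far denser and more heterogeneous than a clean
i+4 ladder. Passing fixture tests certifies the algorithmic contracts
(sparsity counts, refinement, soundness of labels), not biological
accuracy of any particular decomposition; on real proteins the results
are known to be sensitive to protonation and to the energy cutoff, which
is why both are explicit inputs.

## Numerical choices and problem sizes

Geometry uses double precision throughout; the only tolerances are the
documented chemical ones (0.4 Å covalent, 0.25 Å van der Waals slack,
gates above). Detection is rigid-motion invariant to ≈ 1e−9 (verified by
test). Tie-breaks are everywhere lexicographic on atom serials or labels.
The exhaustive oracles are vectorized over subset bitmasks and bounded at
|V| ≤ 8; property suites run the game against them on hundreds of seeded
random multigraphs with |V| ≤ 6, |E| ≤ 40, and the dilution/redundancy/
coloring properties on helices of 6–8 residues — sizes at which the
exhaustive oracles are airtight and the whole suite completes in seconds,
while the code paths exercised are identical to those used on larger
molecules.

## Known limitations

* No mmCIF input, bioassembly/crystal expansion, or structure repair
  beyond gap reporting; no hydrogen placement (protonated input
  required).
* Nucleic acids are handled by the distance fallback and backbone
  linkage only — no base-pair or stacking interactions.
* Components (and everything downstream) require l = k; periodic or
  symmetry-reduced (quotient-graph) rigidity is out of scope.
* The optional peptide-unit body grouping is not implemented; atom-hub
  bodies give equivalent generic results and keep the model fully
  specified.
* No 3D rendering; coloring output is data for external viewers.
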