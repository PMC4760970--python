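"""The (k,l)-pebble game on multigraphs.

Decides independence of edges in the (k,l)-sparsity matroid (every vertex
subset S with |S| >= 2 spans at most k|S| - l independent edges), returns
the matroid rank, the redundant edges, per-vertex free pebbles, and — for
l = k, the body-bar-hinge case — the decomposition into rigid components.
With k = l = 6 the six pebbles per vertex are a rigid body's six degrees
of freedom in 3D, and components are the rigid clusters of the framework.

Exhaustive brute-force oracles (`oracle_rank`, `oracle_components`,
`verify_sparsity`) are provided for small graphs; they share nothing with
the game implementation beyond the sparsity definition itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import Multigraph

__all__ = [
    "PebbleParams",
    "PebbleResult",
    "PebbleError",
    "run_pebble_game",
    "free_dof",
    "oracle_rank",
    "oracle_components",
    "verify_sparsity",
]


class PebbleError(ValueError):
    pass


@dataclass(frozen=True)
class PebbleParams:
    """k pebbles per vertex, sparsity offset l; defaults give the
    (6,6)-pebble game of 3D body-bar-hinge rigidity."""

    k: int = 6
    l: int = 6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.l <= 2 * self.k - 1:
            raise ValueError("l must satisfy 0 <= l <= 2k-1")


@dataclass
class PebbleResult:
    independent: list[tuple[int, int, int]]
    redundant: list[tuple[int, int, int]]
    free_pebbles: dict[int, int]
    # None when l != k: component detection is only implemented for the
    # body-framework case (rank/redundancy are exact for every (k, l))
    components: list[frozenset[int]] | None
    rank: int
    params: PebbleParams = field(default_factory=PebbleParams)

    @property
    def n_edges(self) -> int:
        return len(self.independent) + len(self.redundant)


class _GameState:
    """Mutable pebble-game state: pebble counts plus the directed graph of
    accepted (independent) edges."""

    def __init__(self, vertices, k: int):
        self.peb = {v: k for v in vertices}
        self.out = {v: [] for v in vertices}  # directed multi-adjacency

    def find_pebble(self, start: int, forbidden: tuple[int, ...]) -> bool:
        """DFS for a free pebble reachable from ``start`` (not sitting on a
        forbidden vertex); on success move it to ``start``, reversing the
        path, and return True."""
        parent = {start: None}
        stack = [start]
        target = None
        while stack:
            v = stack.pop()
            if v != start and v not in forbidden and self.peb[v] > 0:
                target = v
                break
            for w in self.out[v]:
                if w not in parent:
                    parent[w] = v
                    stack.append(w)
        if target is None:
            return False
        # reverse the path start -> ... -> target
        v = target
        while parent[v] is not None:
            p = parent[v]
            self.out[p].remove(v)
            self.out[v].append(p)
            v = p
        self.peb[target] -= 1
        self.peb[start] += 1
        return True

    def gather(self, u: int, v: int, need: int) -> bool:
        """Try to accumulate ``need`` pebbles on {u, v}; True on success."""
        while self.peb[u] + self.peb[v] < need:
            if not (self.find_pebble(u, (u, v)) or self.find_pebble(v, (u, v))):
                return False
        return True


def run_pebble_game(graph: Multigraph,
                    params: PebbleParams | None = None) -> PebbleResult:
    """Play the (k,l)-pebble game over all edges of ``graph``.

    Edges are inserted in a deterministic order (sorted by connection tag,
    then endpoints) so the identity of redundant edges is reproducible;
    rank, free pebbles, and components are invariant under any order.
    Components are computed for l == k (rigid-pair equivalence classes,
    valid because for body frameworks rigidity composes through a shared
    body); for l != k, rank and redundancy are still exact but the result's
    components field is None.
    """
    params = params or PebbleParams()
    k, l = params.k, params.l
    for u, v, _t in graph.edges:
        if u == v:
            raise PebbleError("loops are inadmissible for l >= k")
    state = _GameState(graph.vertices, k)
    independent: list[tuple[int, int, int]] = []
    redundant: list[tuple[int, int, int]] = []
    for edge in sorted(graph.edges, key=lambda e: (e[2], e[0], e[1])):
        u, v, _t = edge
        if state.gather(u, v, l + 1):
            if state.peb[u] == 0:
                u, v = v, u
            state.peb[u] -= 1
            state.out[u].append(v)
            independent.append(edge)
        else:
            redundant.append(edge)

    if l == k:
        components = _components_lk(state, graph, l)
    else:
        components = [] if not graph.edges else None

    return PebbleResult(
        independent=independent,
        redundant=redundant,
        free_pebbles=dict(state.peb),
        components=components,
        rank=len(independent),
        params=params,
    )


def _components_lk(state: _GameState, graph: Multigraph, l: int
                   ) -> list[frozenset[int]]:
    """Rigid components for l == k as equivalence classes of the rigid-pair
    relation: u ~ v iff at most l pebbles can be gathered onto {u, v}.

    Pebble gathering only redistributes pebbles and reorients independent
    edges, both of which leave the matroid state (and hence later queries)
    unchanged, so the probes need no rollback.  Vertices without incident
    independent edges cannot belong to any component and are skipped.
    """
    incident: set[int] = set()
    for v, outs in state.out.items():
        if outs:
            incident.add(v)
            incident.update(outs)
    classes: list[list[int]] = []
    for v in sorted(incident):
        for cls in classes:
            if not state.gather(cls[0], v, l + 1):
                cls.append(v)
                break
        else:
            classes.append([v])
    comps = [frozenset(c) for c in classes if len(c) >= 2]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def free_dof(result: PebbleResult) -> int:
    """Total free degrees of freedom: sum of free pebbles = k|V| - rank.

    For any non-empty connected graph with k = l = 6 this is >= 6 (the
    trivial rigid-body motions of the whole framework).
    """
    if not result.free_pebbles:
        raise PebbleError("free DoF is undefined for an empty graph")
    return sum(result.free_pebbles.values())


# ---------------------------------------------------------------------------
# Exhaustive oracles (small graphs only)
# ---------------------------------------------------------------------------

_ORACLE_MAX_V = 8
_ORACLE_MAX_E = 48


def _vertex_index(graph: Multigraph) -> dict[int, int]:
    return {v: i for i, v in enumerate(sorted(graph.vertices))}


def _edge_masks(graph: Multigraph, index: dict[int, int]) -> np.ndarray:
    return np.array(
        [(1 << index[u]) | (1 << index[v]) for u, v, _t in graph.edges],
        dtype=np.int64,
    ) if graph.edges else np.zeros(0, dtype=np.int64)


def _is_sparse(masks: np.ndarray, subsets: np.ndarray,
               popcounts: np.ndarray, k: int, l: int) -> bool:
    """Exhaustive (k,l)-sparsity check of an edge multiset (as endpoint
    bitmasks) against every vertex subset of size >= 2."""
    if len(masks) == 0:
        return True
    inside = (masks[:, None] & ~subsets[None, :]) == 0
    counts = inside.sum(axis=0)
    caps = k * popcounts - l
    ok = popcounts >= 2
    return bool(np.all(counts[ok] <= caps[ok]))


def _subset_tables(n: int):
    subsets = np.arange(1 << n, dtype=np.int64)
    popcounts = np.array([bin(s).count("1") for s in subsets], dtype=np.int64)
    return subsets, popcounts


def _greedy_rank(masks: np.ndarray, subsets, popcounts, k: int, l: int) -> int:
    chosen: list[int] = []
    for m in masks:
        trial = np.array(chosen + [m], dtype=np.int64)
        if _is_sparse(trial, subsets, popcounts, k, l):
            chosen.append(int(m))
    return len(chosen)


def _check_oracle_size(graph: Multigraph) -> None:
    if graph.n_vertices > _ORACLE_MAX_V or graph.n_edges > _ORACLE_MAX_E:
        raise PebbleError(
            f"oracle limited to |V| <= {_ORACLE_MAX_V}, |E| <= {_ORACLE_MAX_E} "
            f"(got |V|={graph.n_vertices}, |E|={graph.n_edges})")


def oracle_rank(graph: Multigraph, params: PebbleParams | None = None) -> int:
    """Brute-force (k,l)-matroid rank by greedy augmentation with exhaustive
    sparsity verification over all vertex subsets.  Small graphs only."""
    params = params or PebbleParams()
    _check_oracle_size(graph)
    index = _vertex_index(graph)
    masks = _edge_masks(graph, index)
    subsets, popcounts = _subset_tables(len(index))
    return _greedy_rank(masks, subsets, popcounts, params.k, params.l)


def oracle_components(graph: Multigraph,
                      params: PebbleParams | None = None
                      ) -> list[frozenset[int]]:
    """All maximal vertex sets S, |S| >= 2, whose induced subgraph has
    matroid rank exactly k|S| - l.  Exhaustive; small graphs only."""
    params = params or PebbleParams()
    _check_oracle_size(graph)
    k, l = params.k, params.l
    index = _vertex_index(graph)
    rev = {i: v for v, i in index.items()}
    masks = _edge_masks(graph, index)
    n = len(index)
    subsets, popcounts = _subset_tables(n)
    rigid_masks: list[int] = []
    for s in range(1 << n):
        pc = int(popcounts[s])
        if pc < 2:
            continue
        induced = masks[(masks & ~s) == 0]
        if len(induced) < k * pc - l:
            continue
        if _greedy_rank(induced, subsets, popcounts, k, l) == k * pc - l:
            rigid_masks.append(s)
    maximal = [s for s in rigid_masks
               if not any(t != s and (s & ~t) == 0 for t in rigid_masks)]
    comps = [frozenset(rev[i] for i in range(n) if s >> i & 1)
             for s in maximal]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def verify_sparsity(edges: list[tuple[int, int, int]],
                    vertices: list[int],
                    params: PebbleParams | None = None) -> bool:
    """Exhaustively check that an edge multiset is (k,l)-sparse."""
    params = params or PebbleParams()
    graph = Multigraph(list(vertices), list(edges))
    _check_oracle_size(graph)
    index = _vertex_index(graph)
    masks = _edge_masks(graph, index)
    subsets, popcounts = _subset_tables(len(index))
    return _is_sparse(masks, subsets, popcounts, params.k, params.l)
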