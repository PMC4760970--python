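"""Visualization-ready cluster coloring.

Three schemes: plain size-based coloring of one decomposition;
dilution-consistent coloring of a whole series, where on every split the
largest child keeps the parent's color; and consistent coloring of two
arbitrary decompositions of the same molecule via a Gale–Shapley stable
matching on shared-atom counts, so corresponding clusters get the same
color across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .apps import DilutionSeries, match_parent
from .clusters import RigidClusterDecomposition, overlap_matrix

__all__ = [
    "Palette",
    "ColorAssignment",
    "ColoringError",
    "DEFAULT_COLORS",
    "color_by_size",
    "color_dilution_series",
    "match_decompositions",
]


class ColoringError(ValueError):
    pass


DEFAULT_COLORS = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#ffff33",
    "#a65628", "#f781bf", "#1b9e77", "#d95f02", "#7570b3", "#66a61e",
)
NEUTRAL = "#c8c8c8"


@dataclass
class Palette:
    """Ordered distinct colors, a neutral for sub-threshold clusters, and
    the dominant-cluster size threshold (atoms)."""

    colors: tuple[str, ...] = DEFAULT_COLORS
    neutral: str = NEUTRAL
    threshold: int = 5

    def __post_init__(self) -> None:
        self.colors = tuple(self.colors)
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("palette colors must be distinct")
        if self.neutral in self.colors:
            raise ValueError("neutral color must not be in the main list")


@dataclass
class ColorAssignment:
    """Map cluster label -> color; injective over non-neutral clusters."""

    colors: dict[int, str] = field(default_factory=dict)
    neutral: str = NEUTRAL
    cycled: bool = False   # palette exhausted and colors were recycled

    def color_of(self, label: int) -> str:
        return self.colors.get(label, self.neutral)


def color_by_size(decomposition: RigidClusterDecomposition,
                  palette: Palette | None = None) -> ColorAssignment:
    """Dominant clusters (>= threshold atoms) get palette colors in label
    order; the rest are neutral.  If there are more dominant clusters than
    colors, colors cycle and the assignment is flagged."""
    palette = palette or Palette()
    assignment = ColorAssignment(neutral=palette.neutral)
    idx = 0
    for cluster in decomposition.clusters:
        if cluster.size >= palette.threshold:
            if idx >= len(palette.colors):
                assignment.cycled = True
            assignment.colors[cluster.label] = (
                palette.colors[idx % len(palette.colors)])
            idx += 1
        else:
            assignment.colors[cluster.label] = palette.neutral
    return assignment


class _ColorWell:
    """Hands out colors never used before in this coloring context."""

    def __init__(self, palette: Palette):
        self.palette = palette
        self.used: set[str] = set()
        self._auto = 0

    def take(self, color: str) -> str:
        self.used.add(color)
        return color

    def fresh(self) -> str:
        for c in self.palette.colors:
            if c not in self.used:
                return self.take(c)
        self._auto += 1
        return self.take(f"auto-{self._auto}")


def color_dilution_series(series: DilutionSeries,
                          palette: Palette | None = None
                          ) -> list[ColorAssignment]:
    """Consistent coloring along a dilution: step 0 is colored by size; at
    every later step each parent's color is inherited by its largest child
    (ties to the smallest atom serial), other above-threshold children get
    colors never used before in the series, sub-threshold children are
    neutral.  Raises ColoringError naming the first non-refining step."""
    palette = palette or Palette()
    well = _ColorWell(palette)
    first = color_by_size(series.steps[0].decomposition, palette)
    for c in first.colors.values():
        if c != palette.neutral:
            well.take(c)
    assignments = [first]
    for t in range(1, len(series.steps)):
        prev_dec = series.steps[t - 1].decomposition
        cur_dec = series.steps[t].decomposition
        prev_colors = assignments[-1]
        children: dict[int, list] = {}
        for cluster in cur_dec.clusters:
            parent, contained = match_parent(prev_dec, cluster)
            if not contained or parent is None:
                raise ColoringError(
                    f"step {t} does not refine step {t - 1}: cluster "
                    f"{cluster.label} is not contained in a previous cluster")
            children.setdefault(parent, []).append(cluster)
        cur = ColorAssignment(neutral=palette.neutral)
        for parent in sorted(children):
            kids = sorted(children[parent],
                          key=lambda c: (-c.size, min(c.atoms)))
            cur.colors[kids[0].label] = prev_colors.color_of(parent)
            for kid in kids[1:]:
                if kid.size >= palette.threshold:
                    cur.colors[kid.label] = well.fresh()
                else:
                    cur.colors[kid.label] = palette.neutral
        assignments.append(cur)
    return assignments


# ---------------------------------------------------------------------------
# Stable-matching consistent coloring of two decompositions
# ---------------------------------------------------------------------------

def _preferences(overlap, labels_self, labels_other, transpose: bool):
    prefs = {}
    for i, la in enumerate(labels_self):
        row = overlap[:, i] if transpose else overlap[i, :]
        ranked = [lb for j, lb in enumerate(labels_other) if row[j] > 0]
        ranked.sort(key=lambda lb: (-row[labels_other.index(lb)], lb))
        prefs[la] = ranked
    return prefs


def match_decompositions(a: RigidClusterDecomposition,
                         b: RigidClusterDecomposition,
                         palette: Palette | None = None):
    """Stable one-to-one matching of clusters by shared-atom count.

    Each side ranks the other's clusters by overlap (ties by label);
    zero-overlap pairs are mutually unacceptable; side ``a`` proposes, so
    the result is the a-optimal stable matching and is deterministic.
    Returns (matching dict a_label->b_label, assignment for a,
    assignment for b): matched pairs share a color, unmatched
    above-threshold clusters get fresh colors, the rest are neutral.
    """
    palette = palette or Palette()
    mat = overlap_matrix(a, b)  # raises on disjoint atom universes
    labels_a = [c.label for c in a.clusters]
    labels_b = [c.label for c in b.clusters]
    pref_a = _preferences(mat, labels_a, labels_b, transpose=False)
    pref_b = _preferences(mat, labels_b, labels_a, transpose=True)
    rank_b = {lb: {la: r for r, la in enumerate(pref_b[lb])}
              for lb in labels_b}

    # Gale–Shapley, proposers = a
    next_prop = {la: 0 for la in labels_a}
    engaged_b: dict[int, int] = {}
    free = [la for la in labels_a if pref_a[la]]
    free.reverse()  # pop() proposes in ascending label order
    while free:
        la = free.pop()
        while next_prop[la] < len(pref_a[la]):
            lb = pref_a[la][next_prop[la]]
            next_prop[la] += 1
            if la not in rank_b[lb]:
                continue
            cur = engaged_b.get(lb)
            if cur is None:
                engaged_b[lb] = la
                break
            if rank_b[lb][la] < rank_b[lb][cur]:
                engaged_b[lb] = la
                free.append(cur)
                break
    matching = {la: lb for lb, la in engaged_b.items()}

    size_a = {c.label: c.size for c in a.clusters}
    size_b = {c.label: c.size for c in b.clusters}
    well = _ColorWell(palette)
    assign_a = ColorAssignment(neutral=palette.neutral)
    assign_b = ColorAssignment(neutral=palette.neutral)
    for la in labels_a:
        if la in matching:
            shared = well.fresh()
            assign_a.colors[la] = shared
            assign_b.colors[matching[la]] = shared
        elif size_a[la] >= palette.threshold:
            assign_a.colors[la] = well.fresh()
        else:
            assign_a.colors[la] = palette.neutral
    for lb in labels_b:
        if lb in assign_b.colors:
            continue
        if size_b[lb] >= palette.threshold:
            assign_b.colors[lb] = well.fresh()
        else:
            assign_b.colors[lb] = palette.neutral
    return matching, assign_a, assign_b
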