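"""Protein peeling: recursive splitting of the chain into Protein Units.

A Protein Unit (PU) is a contiguous fragment of intermediate size (between
secondary structures and domains) with many internal contacts and few
contacts to the rest of the chain.  Peeling greedily bipartitions (or
tripartitions) segments of the chain so as to maximize a partition index
that rewards high intra-segment and low inter-segment contact mass; each
greedy step defines one peeling level.

The partition index for sub-segments s_1..s_m with intra masses I_k and
total inter mass X is

    PI = (G - X^2) / (G + X^2),    G = (prod_k I_k)^(2/m)

which is bounded in [-1, 1], scale-free, and equal to 1 exactly when the
sub-segments share no contact mass (X = 0) while each is internally
connected (I_k > 0).  The form is isolated behind :func:`partition_index`
so that alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_map import ContactMap, contact_mass

#: Name of the partition-criterion functional form, echoed in output metadata.
PI_FORM = "normalized-geometric-intra-vs-squared-inter"

DEFAULT_MIN_PU_SIZE = 15
DEFAULT_MAX_PUS = 16
DEFAULT_MAX_CUTS = 2
#: Maximum admissible coupling ratio X^2/G for a split to be accepted.
#: Equivalent to requiring PI >= (1 - t) / (1 + t) ~= 0.905 at t = 0.05.
DEFAULT_MAX_COUPLING = 0.05

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class ProteinUnit:
    """A contiguous residue interval [start, end] produced by peeling."""

    start: int
    end: int
    level: int = 0
    compaction_index: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SplitResult:
    cut_positions: tuple[int, ...]
    partition_index: float


@dataclass
class PeelingTree:
    """All peeling levels; level k is the frontier after k greedy splits."""

    levels: list[list[ProteinUnit]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels) - 1

    @property
    def terminal_pus(self) -> list[ProteinUnit]:
        return self.levels[-1]


class _PrefixMass:
    """O(1) rectangle sums over the contact matrix via a 2D prefix sum."""

    def __init__(self, probs: np.ndarray):
        n = probs.shape[0]
        self._p = np.zeros((n + 1, n + 1))
        self._p[1:, 1:] = probs.cumsum(axis=0).cumsum(axis=1)

    def rect(self, r1: int, r2: int, c1: int, c2: int) -> float:
        """Sum of probs[r1..r2, c1..c2], all bounds 1-based inclusive."""
        p = self._p
        return float(p[r2, c2] - p[r1 - 1, c2] - p[r2, c1 - 1] + p[r1 - 1, c1 - 1])

    def intra(self, a: int, b: int) -> float:
        return self.rect(a, b, a, b) / 2.0

    def inter(self, a: int, b: int, c: int, d: int) -> float:
        return self.rect(a, b, c, d)


def _pi_from_masses(intra_masses, inter_mass: float) -> float:
    m = len(intra_masses)
    g = float(np.prod(intra_masses)) ** (2.0 / m)
    x2 = inter_mass * inter_mass
    denom = g + x2
    if denom == 0.0:
        return 0.0
    return (g - x2) / denom


def _segments_from_cuts(segment: tuple[int, int], cuts) -> list[tuple[int, int]]:
    start, end = segment
    bounds = [start - 1, *cuts, end]
    return [(bounds[k] + 1, bounds[k + 1]) for k in range(len(bounds) - 1)]


def partition_index(
    cm: ContactMap,
    segment: tuple[int, int],
    cuts,
    min_pu_size: int = 1,
) -> float:
    """Partition index of cutting ``segment`` after each position in ``cuts``."""
    start, end = segment
    cuts = tuple(sorted(cuts))
    if not cuts or len(cuts) > 2:
        raise ValueError("cuts must hold 1 or 2 positions")
    for c in cuts:
        if not start <= c < end:
            raise ValueError(f"cut {c} not strictly inside segment {segment}")
    subs = _segments_from_cuts(segment, cuts)
    for a, b in subs:
        if b - a + 1 < min_pu_size:
            raise ValueError(f"sub-segment {a}-{b} shorter than min_pu_size={min_pu_size}")
    sets = [frozenset(range(a, b + 1)) for a, b in subs]
    intra = [contact_mass(cm, s, s) for s in sets]
    inter = 0.0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter += contact_mass(cm, sets[i], sets[j])
    return _pi_from_masses(intra, inter)


def _best_split_prefix(
    prefix: _PrefixMass,
    segment: tuple[int, int],
    min_pu_size: int,
    max_cuts: int,
    max_coupling: float,
) -> SplitResult | None:
    start, end = segment
    best: SplitResult | None = None
    best_pi = -np.inf

    # 1-cut candidates, left to right (earliest candidate wins ties, which
    # realizes the fewest-cuts-then-leftmost tie-break together with the
    # enumeration order below).
    for c in range(start + min_pu_size - 1, end - min_pu_size + 1):
        i1 = prefix.intra(start, c)
        i2 = prefix.intra(c + 1, end)
        x = prefix.inter(start, c, c + 1, end)
        pi = _pi_from_masses((i1, i2), x)
        if pi > best_pi + _TIE_EPS:
            best_pi = pi
            best = SplitResult((c,), pi)

    if max_cuts >= 2:
        for c1 in range(start + min_pu_size - 1, end - 2 * min_pu_size + 1):
            i1 = prefix.intra(start, c1)
            for c2 in range(c1 + min_pu_size, end - min_pu_size + 1):
                i2 = prefix.intra(c1 + 1, c2)
                i3 = prefix.intra(c2 + 1, end)
                x = (
                    prefix.inter(start, c1, c1 + 1, c2)
                    + prefix.inter(start, c1, c2 + 1, end)
                    + prefix.inter(c1 + 1, c2, c2 + 1, end)
                )
                pi = _pi_from_masses((i1, i2, i3), x)
                if pi > best_pi + _TIE_EPS:
                    best_pi = pi
                    best = SplitResult((c1, c2), pi)

    if best is None:
        return None
    # accept only nearly decoupled splits: X^2/G <= max_coupling,
    # i.e. PI >= (1 - max_coupling) / (1 + max_coupling)
    if best.partition_index < (1.0 - max_coupling) / (1.0 + max_coupling):
        return None
    return best


def best_split(
    cm: ContactMap,
    segment: tuple[int, int],
    min_pu_size: int = DEFAULT_MIN_PU_SIZE,
    max_cuts: int = DEFAULT_MAX_CUTS,
    max_coupling: float = DEFAULT_MAX_COUPLING,
) -> SplitResult | None:
    """Exhaustively scan all admissible 1- and 2-cut splits of a segment.

    Returns the cut set with maximal partition index, or None when no
    admissible cut exists or the best split leaves the sub-segments too
    coupled (X^2/G > max_coupling).  Ties are broken toward fewer cuts,
    then the leftmost cut positions.
    """
    prefix = _PrefixMass(cm.probs)
    return _best_split_prefix(prefix, segment, min_pu_size, max_cuts, max_coupling)


def peel(
    cm: ContactMap,
    min_pu_size: int = DEFAULT_MIN_PU_SIZE,
    max_pus: int = DEFAULT_MAX_PUS,
    max_cuts: int = DEFAULT_MAX_CUTS,
    max_coupling: float = DEFAULT_MAX_COUPLING,
) -> PeelingTree:
    """Iterative greedy peeling of the whole chain.

    At each iteration the frontier PU whose best split has the globally
    highest partition index is split; the resulting frontier is recorded as
    the next level.  Stops when no PU is splittable or the frontier has
    reached ``max_pus`` units.
    """
    n = cm.n
    prefix = _PrefixMass(cm.probs)
    frontier: list[tuple[int, int]] = [(1, n)]
    tree = PeelingTree(levels=[_frontier_units(cm, frontier, level=0)])
    split_cache: dict[tuple[int, int], SplitResult | None] = {}

    while len(frontier) < max_pus:
        candidates = []
        for seg in frontier:
            if seg not in split_cache:
                if seg[1] - seg[0] + 1 < 2 * min_pu_size:
                    split_cache[seg] = None
                else:
                    split_cache[seg] = _best_split_prefix(
                        prefix, seg, min_pu_size, max_cuts, max_coupling
                    )
            if split_cache[seg] is not None:
                candidates.append((seg, split_cache[seg]))
        if not candidates:
            break
        # globally best PI; ties toward the leftmost segment
        seg, split = max(
            candidates, key=lambda item: (item[1].partition_index, -item[0][0])
        )
        new_segments = _segments_from_cuts(seg, split.cut_positions)
        pos = frontier.index(seg)
        frontier = frontier[:pos] + new_segments + frontier[pos + 1:]
        tree.levels.append(_frontier_units(cm, frontier, level=len(tree.levels)))
    return tree


def _frontier_units(cm: ContactMap, frontier, level: int) -> list[ProteinUnit]:
    return [
        ProteinUnit(start=s, end=e, level=level,
                    compaction_index=compaction_index(cm, (s, e)))
        for s, e in frontier
    ]


def compaction_index(cm: ContactMap, pu: tuple[int, int]) -> float:
    """Fraction of a PU's non-local contact mass that is internal.

    Only pairs with sequence separation >= 3 count.  CI = 1 means the unit
    shares no non-local contacts with the rest of the chain; defined as 0
    when the unit has no non-local contact mass at all.
    """
    start, end = pu
    nl = cm.nonlocal_view()
    unit = frozenset(range(start, end + 1))
    rest = frozenset(range(1, nl.n + 1)) - unit
    intra = contact_mass(nl, unit, unit)
    inter = contact_mass(nl, unit, rest) if rest else 0.0
    denom = intra + inter
    if denom == 0.0:
        return 0.0
    return intra / denom
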