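"""Domain assembly: merge Protein Units into alternative domain partitions.

Starting from the terminal PUs of peeling, an agglomerative beam search
gradually merges units into domains.  A merge of units A and B is ranked by
their separation

    S(A, B) = inter_mass(A, B) / sqrt(intra_mass(A) * intra_mass(B))

(high S = many shared contacts = good merge candidates) with ties broken by
the compactness of the merged domain,

    C(U) = intra_mass(U) / |U|    (contact mass per residue).

Every partition visited on the way from |PUs| domains down to a single
domain is recorded, scored for quality on a 1-5 scale, and kept if it falls
in the acceptance range (quality >= 2).  Domains may be unions of
non-adjacent PUs, so sequence-discontinuous domains arise naturally.

The quality step function compares two ratios against fixed steps:
rho = non-local inter-domain mass / total non-local mass (lower = better
separated) and kappa = min domain compactness / whole-chain compactness
(higher = each domain at least as dense as the chain).  The A-index
(ambiguity index) of the resulting partition set is the largest A such that
A partitions have quality >= A — an h-index over partition qualities.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .contact_map import ContactMap, contact_mass
from .peeling import ProteinUnit

logger = logging.getLogger(__name__)

DEFAULT_BEAM_WIDTH = 3

#: Quality step function: (max rho, min kappa, quality); first match wins,
#: fall-through is quality 1.  Quality >= 2 is the acceptance range.
QUALITY_STEPS = (
    (0.03, 0.9, 5),
    (0.06, 0.8, 4),
    (0.10, 0.7, 3),
    (0.15, 0.6, 2),
)
ACCEPTABLE_MIN_QUALITY = 2


@dataclass(frozen=True)
class Domain:
    pu_members: frozenset
    residue_set: frozenset
    compactness: float

    def segments(self) -> list[tuple[int, int]]:
        """Maximal contiguous runs of the residue set, sorted."""
        out = []
        for _, grp in itertools.groupby(
            enumerate(sorted(self.residue_set)), key=lambda t: t[1] - t[0]
        ):
            block = [g[1] for g in grp]
            out.append((block[0], block[-1]))
        return out


@dataclass
class Partition:
    domains: list[Domain]
    quality: int
    is_acceptable: bool
    separation_fraction: float
    min_compactness_ratio: float

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def mean_compactness(self) -> float:
        return float(np.mean([d.compactness for d in self.domains]))

    def domain_of(self, residue: int) -> int:
        for k, d in enumerate(self.domains):
            if residue in d.residue_set:
                return k
        raise KeyError(residue)


@dataclass(frozen=True)
class JunctionStat:
    position: int  # boundary between residues position and position+1
    count: int
    frequency: float
    weight: float


@dataclass
class PartitionSet:
    partitions: list[Partition]
    optimal_index: int
    a_index: int
    junctions: list[JunctionStat] = field(default_factory=list)
    domain_frequency: list[tuple[frozenset, int]] = field(default_factory=list)

    @property
    def optimal(self) -> Partition:
        return self.partitions[self.optimal_index]


def separation(cm: ContactMap, unit_a, unit_b) -> float:
    """Normalized inter-unit contact mass S = X / sqrt(I_A * I_B)."""
    a, b = frozenset(unit_a), frozenset(unit_b)
    if a & b:
        raise ValueError("separation of overlapping sets is undefined")
    inter = contact_mass(cm, a, b)
    ia = contact_mass(cm, a, a)
    ib = contact_mass(cm, b, b)
    if ia == 0.0 or ib == 0.0:
        return inter if inter > 0.0 else 0.0
    return inter / math.sqrt(ia * ib)


def compactness(cm: ContactMap, unit) -> float:
    """Contact density C = intra mass per residue."""
    u = frozenset(unit)
    if not u:
        raise ValueError("compactness of an empty set is undefined")
    return contact_mass(cm, u, u) / len(u)


class _PUMasses:
    """Additive PU-level masses so domain statistics are O(#PUs)."""

    def __init__(self, cm: ContactMap, pus: list[tuple[int, int]]):
        self.pus = pus
        self.sets = [frozenset(range(s, e + 1)) for s, e in pus]
        k = len(pus)
        self.intra = np.array([contact_mass(cm, s, s) for s in self.sets])
        self.inter = np.zeros((k, k))
        nl = cm.nonlocal_view()
        self.intra_nl = np.array([contact_mass(nl, s, s) for s in self.sets])
        self.inter_nl = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                m = contact_mass(cm, self.sets[i], self.sets[j])
                self.inter[i, j] = self.inter[j, i] = m
                m_nl = contact_mass(nl, self.sets[i], self.sets[j])
                self.inter_nl[i, j] = self.inter_nl[j, i] = m_nl
        self.n_residues = cm.n
        self.total_nonlocal = float(self.intra_nl.sum() + np.triu(self.inter_nl, 1).sum())
        self.chain_compactness = float(self.intra.sum() + np.triu(self.inter, 1).sum()) / cm.n

    def domain_intra(self, members) -> float:
        idx = sorted(members)
        m = float(self.intra[idx].sum())
        for i, j in itertools.combinations(idx, 2):
            m += self.inter[i, j]
        return m

    def domain_size(self, members) -> int:
        return sum(len(self.sets[i]) for i in members)

    def domain_compactness(self, members) -> float:
        return self.domain_intra(members) / self.domain_size(members)

    def inter_domains(self, members_a, members_b) -> float:
        return float(sum(self.inter[i, j] for i in members_a for j in members_b))

    def inter_domains_nonlocal(self, members_a, members_b) -> float:
        return float(sum(self.inter_nl[i, j] for i in members_a for j in members_b))

    def residue_set(self, members) -> frozenset:
        out = set()
        for i in members:
            out |= self.sets[i]
        return frozenset(out)


def _state_key(state) -> tuple:
    return tuple(sorted(tuple(sorted(d)) for d in state))


def _quality_from_state(masses: _PUMasses, state) -> tuple[int, float, float]:
    """(quality, rho, kappa) of a partition given as PU-member groups."""
    if len(state) == 1:
        return 5, 0.0, 1.0  # single-domain convention
    rho_num = 0.0
    for da, db in itertools.combinations(state, 2):
        rho_num += masses.inter_domains_nonlocal(da, db)
    rho = rho_num / masses.total_nonlocal if masses.total_nonlocal > 0 else 0.0
    c_min = min(masses.domain_compactness(d) for d in state)
    kappa = c_min / masses.chain_compactness if masses.chain_compactness > 0 else 0.0
    for rho_max, kappa_min, q in QUALITY_STEPS:
        if rho <= rho_max and kappa >= kappa_min:
            return q, rho, kappa
    return 1, rho, kappa


def partition_quality(cm: ContactMap, domain_sets) -> int:
    """Quality 1-5 of a partition given as a list of residue sets."""
    sets = [frozenset(s) for s in domain_sets]
    union = set()
    for s in sets:
        if union & s:
            raise ValueError("partition domains overlap")
        union |= s
    if union != set(range(1, cm.n + 1)):
        raise ValueError("partition does not cover 1..N")
    if len(sets) == 1:
        return 5
    nl = cm.nonlocal_view()
    rho_num = sum(
        contact_mass(nl, a, b) for a, b in itertools.combinations(sets, 2)
    )
    full = frozenset(range(1, cm.n + 1))
    total_nl = contact_mass(nl, full, full)
    rho = rho_num / total_nl if total_nl > 0 else 0.0
    c_chain = compactness(cm, full)
    kappa = min(compactness(cm, s) for s in sets) / c_chain if c_chain > 0 else 0.0
    for rho_max, kappa_min, q in QUALITY_STEPS:
        if rho <= rho_max and kappa >= kappa_min:
            return q
    return 1


def merge_states(
    cm: ContactMap,
    terminal_pus,
    beam_width: float = DEFAULT_BEAM_WIDTH,
) -> tuple[_PUMasses, list[tuple]]:
    """Run the agglomerative beam search and return all visited states.

    A state is a partition of PU indices into domains, encoded as a sorted
    tuple of sorted tuples.  Successor merges are ranked by separation S
    (descending), then by the compactness of the merged domain (descending),
    then by the smallest involved PU index; the top ``beam_width`` distinct
    states survive to the next depth, but every generated state is recorded.
    Beam rank 1 therefore reproduces the pure greedy merge path.
    """
    intervals = [
        pu.interval if isinstance(pu, ProteinUnit) else tuple(pu)
        for pu in terminal_pus
    ]
    masses = _PUMasses(cm, intervals)
    k = len(intervals)
    root = tuple((i,) for i in range(k))
    visited = [_state_key(root)]
    seen = {_state_key(root)}
    beam = [_state_key(root)]
    for _depth in range(k - 1):
        ranked = []
        for state in beam:
            for a, b in itertools.combinations(range(len(state)), 2):
                da, db = state[a], state[b]
                inter = masses.inter_domains(da, db)
                ia = masses.domain_intra(da)
                ib = masses.domain_intra(db)
                if ia == 0.0 or ib == 0.0:
                    s_val = inter if inter > 0.0 else 0.0
                else:
                    s_val = inter / math.sqrt(ia * ib)
                merged = tuple(sorted(da + db))
                c_val = masses.domain_compactness(merged)
                succ = _state_key(
                    [merged] + [d for idx, d in enumerate(state) if idx not in (a, b)]
                )
                ranked.append((-s_val, -c_val, min(merged), succ))
        ranked.sort(key=lambda t: t[:3])
        next_beam = []
        for _, _, _, succ in ranked:
            if succ not in seen:
                seen.add(succ)
                visited.append(succ)
            if succ not in next_beam:
                next_beam.append(succ)
            if len(next_beam) >= beam_width:
                break
        # record every generated successor, not only the surviving beam
        for _, _, _, succ in ranked:
            if succ not in seen:
                seen.add(succ)
                visited.append(succ)
        if not next_beam:
            break
        beam = next_beam
    return masses, visited


def merge_search(
    cm: ContactMap,
    terminal_pus,
    beam_width: float = DEFAULT_BEAM_WIDTH,
) -> list[Partition]:
    """All acceptable partitions found by the beam search.

    Duplicate partitions (identical domain residue sets) are removed; the
    result is sorted by number of domains ascending, then quality
    descending.  The single-domain partition is always reachable, so the
    returned list is never empty.
    """
    masses, visited = merge_states(cm, terminal_pus, beam_width)
    partitions: list[Partition] = []
    seen_residue_sets = set()
    for state in visited:
        res_key = frozenset(masses.residue_set(d) for d in state)
        if res_key in seen_residue_sets:
            continue
        seen_residue_sets.add(res_key)
        quality, rho, kappa = _quality_from_state(masses, state)
        if quality < ACCEPTABLE_MIN_QUALITY:
            continue
        domains = [
            Domain(
                pu_members=frozenset(d),
                residue_set=masses.residue_set(d),
                compactness=masses.domain_compactness(d),
            )
            for d in state
        ]
        partitions.append(
            Partition(
                domains=domains,
                quality=quality,
                is_acceptable=True,
                separation_fraction=rho,
                min_compactness_ratio=kappa,
            )
        )
    partitions.sort(key=lambda p: (p.n_domains, -p.quality))
    _assert_covers(partitions, cm.n)
    return partitions


def _assert_covers(partitions: list[Partition], n: int) -> None:
    full = set(range(1, n + 1))
    for p in partitions:
        union = set()
        for d in p.domains:
            if union & d.residue_set:
                raise AssertionError("partition domains overlap")
            union |= d.residue_set
        if union != full:
            raise AssertionError("partition does not cover 1..N")


def select_optimal(partitions: list[Partition]) -> Partition:
    """Optimal partition: most domains among acceptable ones, then the
    highest mean domain compactness, then highest quality, then first."""
    if not partitions:
        raise ValueError("no partitions to select from")
    acceptable = [p for p in partitions if p.is_acceptable]
    if not acceptable:
        single = [p for p in partitions if p.n_domains == 1]
        logger.warning("no acceptable partition; falling back to single-domain")
        if not single:
            raise ValueError("no acceptable partition and no single-domain fallback")
        return single[0]
    best_nd = max(p.n_domains for p in acceptable)
    pool = [p for p in acceptable if p.n_domains == best_nd]
    best_c = max(p.mean_compactness for p in pool)
    pool = [p for p in pool if p.mean_compactness == best_c]
    best_q = max(p.quality for p in pool)
    pool = [p for p in pool if p.quality == best_q]
    return pool[0]


def a_index(qualities) -> int:
    """Largest A such that at least A qualities are >= A (h-index)."""
    qs = list(qualities)
    for q in qs:
        if not (isinstance(q, (int, np.integer)) and 1 <= q <= 5):
            raise ValueError(f"quality {q!r} outside 1..5")
    best = 0
    for a in range(0, 6):
        if sum(1 for q in qs if q >= a) >= a:
            best = a
    return best


def junction_stats(
    partitions: list[Partition],
    terminal_pus,
    n_residues: int,
    include_pu_extremities: bool = True,
) -> list[JunctionStat]:
    """Per-boundary junction statistics across all partitions.

    Boundary k separates residues k and k+1 (chain termini excluded).  A
    partition contains a junction at k when k is an inter-domain boundary
    or, with ``include_pu_extremities``, when k is an internal extremity of
    a PU used to build its domains.  frequency = count / N_d;
    weight = sum over containing partitions of (quality / 5) / N_d.
    """
    if not partitions:
        return []
    n_d = len(partitions)
    intervals = [
        pu.interval if isinstance(pu, ProteinUnit) else tuple(pu)
        for pu in terminal_pus
    ]
    pu_extremities = set()
    for s, e in intervals:
        for k in (s - 1, e):
            if 1 <= k <= n_residues - 1:
                pu_extremities.add(k)

    counts: Counter = Counter()
    weights: Counter = Counter()
    for p in partitions:
        junctions = set()
        if include_pu_extremities:
            junctions |= pu_extremities
        for k in range(1, n_residues):
            if p.domain_of(k) != p.domain_of(k + 1):
                junctions.add(k)
        for k in junctions:
            counts[k] += 1
            weights[k] += p.quality / 5.0
    return [
        JunctionStat(
            position=k,
            count=counts[k],
            frequency=counts[k] / n_d,
            weight=weights[k] / n_d,
        )
        for k in sorted(counts)
    ]


def domain_frequency(partitions: list[Partition]) -> list[tuple[frozenset, int]]:
    """Occurrence count of identical domain residue sets across partitions,
    sorted by descending count (ties by first residue)."""
    counter: Counter = Counter()
    for p in partitions:
        for d in p.domains:
            counter[d.residue_set] += 1
    return sorted(counter.items(), key=lambda kv: (-kv[1], min(kv[0])))


def build_partition_set(
    cm: ContactMap,
    terminal_pus,
    beam_width: float = DEFAULT_BEAM_WIDTH,
    include_pu_extremities: bool = True,
) -> PartitionSet:
    """Full assembly stage: search, optimal selection, A-index, statistics."""
    partitions = merge_search(cm, terminal_pus, beam_width)
    optimal = select_optimal(partitions)
    return PartitionSet(
        partitions=partitions,
        optimal_index=partitions.index(optimal),
        a_index=a_index([p.quality for p in partitions]),
        junctions=junction_stats(
            partitions, terminal_pus, cm.n, include_pu_extremities
        ),
        domain_frequency=domain_frequency(partitions),
    )
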