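"""Domain assembly tests, including brute-force merge-tree and h-index oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protpeel.assembly import (
    Partition,
    a_index,
    build_partition_set,
    compactness,
    domain_frequency,
    junction_stats,
    merge_search,
    merge_states,
    partition_quality,
    select_optimal,
    separation,
)
from protpeel.contact_map import ContactMap, contact_mass
from protpeel.fixtures import make_block_map

from conftest import random_contact_map


def uniform_map(n, p):
    m = np.full((n, n), p)
    np.fill_diagonal(m, 0.0)
    return ContactMap(probs=m, d0=8.0, delta=1.5)


class TestSeparation:
    def test_zero_inter_mass_gives_zero(self):
        cm = make_block_map([4, 4], intra_p=0.9, inter_p=0.0)
        assert separation(cm, range(1, 5), range(5, 9)) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        cm = random_contact_map(rng, 10)
        a, b = frozenset({1, 2, 3}), frozenset({6, 7, 9})
        assert separation(cm, a, b) == pytest.approx(separation(cm, b, a))

    def test_halves_of_one_globule_more_separated_than_two_globules(
        self, two_globule, two_globule_cm
    ):
        (g1s, g1e), (g2s, g2e) = two_globule.globule_intervals
        g1 = frozenset(range(g1s, g1e + 1))
        g2 = frozenset(range(g2s, g2e + 1))
        mid = (g1s + g1e) // 2
        h1 = frozenset(range(g1s, mid + 1))
        h2 = frozenset(range(mid + 1, g1e + 1))
        assert separation(two_globule_cm, h1, h2) > separation(two_globule_cm, g1, g2)

    def test_overlap_rejected(self):
        cm = uniform_map(6, 0.5)
        with pytest.raises(ValueError):
            separation(cm, {1, 2}, {2, 3})


class TestCompactness:
    def test_single_residue_is_zero(self):
        cm = uniform_map(6, 0.5)
        assert compactness(cm, {1}) == 0.0

    def test_uniform_four_residue_value(self):
        cm = uniform_map(6, 0.5)
        # 6 pairs * 0.5 / 4 residues
        assert compactness(cm, {1, 2, 3, 4}) == pytest.approx(0.75)

    def test_adding_isolated_residue_decreases_density(self):
        probs = np.zeros((5, 5))
        probs[:4, :4] = 0.8
        np.fill_diagonal(probs, 0.0)
        cm = ContactMap(probs=probs, d0=8.0, delta=1.5)
        assert compactness(cm, {1, 2, 3, 4, 5}) < compactness(cm, {1, 2, 3, 4})


def all_agglomerative_states(n_pus):
    """Oracle: every partition reachable by successive pair merges (which is
    every set-partition of the PU index set)."""
    def partitions_of(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions_of(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
            yield smaller + [[first]]

    out = set()
    for p in partitions_of(list(range(n_pus))):
        out.add(tuple(sorted(tuple(sorted(b)) for b in p)))
    return out


class TestMergeSearch:
    def test_single_pu_gives_single_partition(self):
        cm = make_block_map([6], intra_p=0.8)
        parts = merge_search(cm, [(1, 6)])
        assert len(parts) == 1
        assert parts[0].n_domains == 1
        assert parts[0].quality == 5

    def test_two_pus_give_at_most_two_partitions(self, two_globule, two_globule_cm):
        pus = two_globule.globule_intervals
        # extend the first PU to cover the linker so the two tile the chain
        pus = [(1, pus[1][0] - 1), (pus[1][0], len(two_globule.structure))]
        parts = merge_search(two_globule_cm, pus)
        assert 1 <= len(parts) <= 2
        assert {p.n_domains for p in parts} <= {1, 2}

    def test_unbounded_beam_visits_every_reachable_state(self):
        """With beam width infinity on 4 PUs, the recorded states are exactly
        the 15 set-partitions of 4 elements (brute-force enumeration)."""
        rng = np.random.default_rng(5)
        cm = random_contact_map(rng, 16)
        pus = [(1, 4), (5, 8), (9, 12), (13, 16)]
        _, visited = merge_states(cm, pus, beam_width=math.inf)
        assert set(visited) == all_agglomerative_states(4)
        assert len(visited) == 15

    def test_five_pus_unbounded_beam_matches_enumeration(self):
        rng = np.random.default_rng(6)
        cm = random_contact_map(rng, 20)
        pus = [(i * 4 + 1, i * 4 + 4) for i in range(5)]
        _, visited = merge_states(cm, pus, beam_width=math.inf)
        assert set(visited) == all_agglomerative_states(5)  # Bell(5) = 52

    def test_partitions_cover_chain_disjointly(self, three_globule_cm):
        from protpeel.peeling import peel

        tree = peel(three_globule_cm, min_pu_size=15)
        parts = merge_search(three_globule_cm, tree.terminal_pus)
        full = set(range(1, three_globule_cm.n + 1))
        for p in parts:
            seen = set()
            for d in p.domains:
                assert not (seen & d.residue_set)
                seen |= d.residue_set
            assert seen == full

    def test_sorted_by_n_domains_then_quality(self, three_globule_cm):
        from protpeel.peeling import peel

        tree = peel(three_globule_cm, min_pu_size=15)
        parts = merge_search(three_globule_cm, tree.terminal_pus)
        keys = [(p.n_domains, -p.quality) for p in parts]
        assert keys == sorted(keys)


class TestPartitionQuality:
    def test_single_domain_is_quality_five(self):
        cm = uniform_map(8, 0.5)
        assert partition_quality(cm, [frozenset(range(1, 9))]) == 5

    def test_linker_cut_beats_globule_cut(self, two_globule, two_globule_cm):
        n = len(two_globule.structure)
        mid = two_globule.linker_midpoints[0]
        at_linker = [frozenset(range(1, mid + 1)), frozenset(range(mid + 1, n + 1))]
        in_globule = [frozenset(range(1, 16)), frozenset(range(16, n + 1))]
        q_linker = partition_quality(two_globule_cm, at_linker)
        q_globule = partition_quality(two_globule_cm, in_globule)
        assert q_linker >= 4
        assert q_globule < q_linker

    def test_non_covering_partition_rejected(self):
        cm = uniform_map(6, 0.5)
        with pytest.raises(ValueError):
            partition_quality(cm, [frozenset({1, 2, 3})])


def _mk_partition(n_domains, quality, mean_c=0.5):
    domains = []
    offset = 1
    for k in range(n_domains):
        rs = frozenset(range(offset, offset + 3))
        offset += 3
        from protpeel.assembly import Domain

        domains.append(Domain(pu_members=frozenset({k}), residue_set=rs,
                              compactness=mean_c))
    return Partition(domains=domains, quality=quality,
                     is_acceptable=quality >= 2, separation_fraction=0.0,
                     min_compactness_ratio=1.0)


class TestSelectOptimal:
    def test_prefers_more_domains(self):
        p2, p3 = _mk_partition(2, 4), _mk_partition(3, 3)
        assert select_optimal([p2, p3]) is p3

    def test_ties_broken_by_mean_compactness(self):
        a = _mk_partition(3, 3, mean_c=0.80)
        b = _mk_partition(3, 3, mean_c=0.75)
        assert select_optimal([b, a]) is a

    def test_single_acceptable_returned(self):
        p1 = _mk_partition(1, 5)
        assert select_optimal([p1]) is p1


class TestAIndex:
    @pytest.mark.parametrize(
        "qualities, expected",
        [([], 0), ([5, 5, 5], 3), ([5, 1, 1], 1), ([3, 3, 3, 3], 3), ([2, 2], 2)],
    )
    def test_known_values(self, qualities, expected):
        assert a_index(qualities) == expected

    def test_matches_definition_on_all_multisets_up_to_six(self):
        """Exhaustive brute force of the definition: the largest A such that
        at least A qualities are >= A."""
        def brute(qs):
            return max(
                (a for a in range(0, 6) if sum(q >= a for q in qs) >= a),
                default=0,
            )

        for size in range(0, 7):
            for qs in itertools.combinations_with_replacement(range(1, 6), size):
                assert a_index(list(qs)) == brute(qs), qs

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            a_index([0, 3])
        with pytest.raises(ValueError):
            a_index([6])

    @given(st.lists(st.integers(min_value=1, max_value=5), max_size=12))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounded_by_count_and_max_quality(self, qs):
        a = a_index(qs)
        assert 0 <= a <= min(len(qs), 5)
        if qs:
            assert a <= max(qs)


class TestJunctionStats:
    def test_junction_in_all_perfect_partitions_has_weight_one(self):
        parts = [_mk_partition(2, 5) for _ in range(3)]
        stats = junction_stats(parts, [(1, 3), (4, 6)], n_residues=6,
                               include_pu_extremities=False)
        assert len(stats) == 1
        j = stats[0]
        assert j.position == 3
        assert j.count == 3
        assert j.frequency == 1.0
        assert j.weight == 1.0

    def test_rare_junction_frequency_and_weight(self):
        parts = [_mk_partition(2, 5)] + [_mk_partition(1, 5) for _ in range(3)]
        # make the single-domain partitions cover the same 6 residues
        from protpeel.assembly import Domain

        for p in parts[1:]:
            p.domains = [Domain(frozenset({0, 1}), frozenset(range(1, 7)), 0.5)]
        stats = junction_stats(parts, [(1, 6)], n_residues=6,
                               include_pu_extremities=False)
        assert len(stats) == 1
        assert stats[0].count == 1
        assert stats[0].frequency == pytest.approx(0.25)
        assert stats[0].weight == pytest.approx(0.25)

    def test_pu_extremities_counted_when_enabled(self):
        parts = [_mk_partition(1, 5)]
        from protpeel.assembly import Domain

        parts[0].domains = [Domain(frozenset({0, 1}), frozenset(range(1, 7)), 0.5)]
        with_ext = junction_stats(parts, [(1, 3), (4, 6)], n_residues=6,
                                  include_pu_extremities=True)
        without = junction_stats(parts, [(1, 3), (4, 6)], n_residues=6,
                                 include_pu_extremities=False)
        assert [j.position for j in with_ext] == [3]
        assert without == []

    def test_weight_never_exceeds_frequency(self, two_globule_cm):
        from protpeel.peeling import peel

        tree = peel(two_globule_cm, min_pu_size=15)
        pset = build_partition_set(two_globule_cm, tree.terminal_pus)
        n_d = len(pset.partitions)
        for j in pset.junctions:
            assert j.frequency == pytest.approx(j.count / n_d)
            assert j.weight <= j.frequency + 1e-12
            assert 0 < j.frequency <= 1


class TestDomainFrequency:
    def test_identical_partitions_count_everything_n_times(self):
        parts = [_mk_partition(2, 5) for _ in range(4)]
        freq = domain_frequency(parts)
        assert all(count == 4 for _, count in freq)

    def test_sorted_by_descending_count(self, two_globule_cm):
        from protpeel.peeling import peel

        tree = peel(two_globule_cm, min_pu_size=15)
        pset = build_partition_set(two_globule_cm, tree.terminal_pus)
        counts = [c for _, c in pset.domain_frequency]
        assert counts == sorted(counts, reverse=True)

    def test_linker_split_domains_present(self, two_globule, two_globule_cm):
        """The linker-cut globule domains appear in the frequency table."""
        from protpeel.peeling import peel

        tree = peel(two_globule_cm, min_pu_size=15)
        pset = build_partition_set(two_globule_cm, tree.terminal_pus)
        mid = two_globule.linker_midpoints[0]
        n = two_globule_cm.n
        halves = [
            rs for rs, _ in pset.domain_frequency
            if len(rs) < n and (abs(max(rs) - mid) <= 2 or abs(min(rs) - 1 - mid) <= 2)
        ]
        assert len(halves) >= 2


class TestOptimalOnFixture:
    def test_two_globule_optimal_is_two_domains(self, two_globule, two_globule_cm):
        from protpeel.peeling import peel

        tree = peel(two_globule_cm, min_pu_size=15)
        pset = build_partition_set(two_globule_cm, tree.terminal_pus)
        opt = pset.optimal
        assert opt.n_domains == 2
        bounds = [
            k for k in range(1, two_globule_cm.n)
            if opt.domain_of(k) != opt.domain_of(k + 1)
        ]
        assert len(bounds) == 1
        assert abs(bounds[0] - two_globule.linker_midpoints[0]) <= 2
        assert pset.optimal in pset.partitions
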