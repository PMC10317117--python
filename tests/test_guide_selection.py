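"""Greedy selection, pooling, grouping, dosing and footprint."""

import numpy as np
import pytest

from repeatclean.genome_io import AnnotationSet, GenomeSequence, IntervalRecord
from repeatclean.guide_discovery import CutSiteIndex, GuideCandidate
from repeatclean.guide_filtering import FilterVerdict
from repeatclean.guide_selection import (
    GuideDesign,
    assign_pools,
    compute_dosing,
    group_for_sequential,
    select_guides,
    targetable_footprint,
)

from conftest import random_seq


def passing_verdict(cand):
    return FilterVerdict(
        guide_id=cand.guide_id,
        protospacer=cand.protospacer,
        gc=0.5,
        gc_pass=True,
        homopolymer=1,
        homopolymer_pass=True,
        dinucleotide_units=1,
        dinucleotide_pass=True,
        hairpin=0,
        hairpin_pass=True,
        efficiency_score=0.8,
        efficiency_pass=True,
        offtarget_hits=0,
    )


def build_candidate(proto, sites):
    cand = GuideCandidate(proto, ("c1", sites[0], "+"), len(sites), len(sites))
    index_sites = [("c1", pos, "+", cand.guide_id) for pos in sites]
    return cand, index_sites


class TestSelectGuides:
    def test_within_guide_spacing_greedy(self):
        cand, sites = build_candidate("ACGT" * 5, [0, 300, 600])
        design = select_guides(
            [cand], [passing_verdict(cand)], CutSiteIndex(sites),
            min_sites=1, min_spacing=500,
        )
        assert design.accepted_counts[cand.guide_id] == 2
        assert design.accepted_sites.positions("c1") == [0, 600]

    def test_site_count_boundary(self):
        sites = [i * 1000 for i in range(24)]
        cand, index_sites = build_candidate("ACGT" * 5, sites)
        with pytest.warns(UserWarning, match="empty design"):
            design = select_guides(
                [cand], [passing_verdict(cand)], CutSiteIndex(index_sites),
                min_sites=25, min_spacing=500,
            )
        assert design.is_empty

    def test_interleaved_guides_first_lexicographic_wins(self):
        # equal counts; sites interleave at 250-bp offsets so accepting
        # the first guide starves the second below min_sites
        a_sites = [i * 500 for i in range(4)]
        b_sites = [250 + i * 500 for i in range(4)]
        a, a_idx = build_candidate("A" * 19 + "C", a_sites)
        b, b_idx = build_candidate("C" * 19 + "A", b_sites)
        index = CutSiteIndex(a_idx + b_idx)
        verdicts = [passing_verdict(a), passing_verdict(b)]
        design = select_guides([a, b], verdicts, index, min_sites=4, min_spacing=500)
        assert [c.guide_id for c in design.guides] == [a.guide_id]

    def test_failed_verdict_excluded(self):
        cand, sites = build_candidate("ACGT" * 5, [0, 1000, 2000])
        v = passing_verdict(cand)
        v.offtarget_hits = 2
        with pytest.warns(UserWarning):
            design = select_guides([cand], [v], CutSiteIndex(sites), min_sites=1)
        assert design.is_empty

    def test_postselection_audit_on_random_designs(self, rng):
        """Accepted sites respect spacing; accepted counts respect the
        threshold; greedy keeps the maximum spaced subset per guide."""
        for trial in range(10):
            cands, verdicts, all_sites = [], [], []
            for g in range(6):
                n = int(rng.integers(3, 30))
                sites = sorted(
                    int(p) for p in rng.choice(20_000, size=n, replace=False)
                )
                proto = random_seq(rng, 20)
                cand, idx = build_candidate(proto, sites)
                cands.append(cand)
                verdicts.append(passing_verdict(cand))
                all_sites.extend(idx)
            design = select_guides(
                cands, verdicts, CutSiteIndex(all_sites),
                min_sites=3, min_spacing=400,
            )
            pos = design.accepted_sites.positions("c1")
            assert all(b - a >= 400 for a, b in zip(pos, pos[1:]))
            assert all(n >= 3 for n in design.accepted_counts.values())

    def test_greedy_spaced_subset_is_maximum(self, rng):
        """Left-to-right greedy picks a maximum-cardinality spaced subset
        (checked against an exhaustive dynamic program)."""

        def dp_max_spaced(sites, d):
            best = [1] * len(sites)
            for i in range(len(sites)):
                for j in range(i):
                    if sites[i] - sites[j] >= d:
                        best[i] = max(best[i], best[j] + 1)
            return max(best, default=0)

        for _ in range(20):
            n = int(rng.integers(1, 15))
            sites = sorted(int(p) for p in rng.choice(3000, n, replace=False))
            cand, idx = build_candidate(random_seq(rng, 20), sites)
            design = select_guides(
                [cand], [passing_verdict(cand)], CutSiteIndex(idx),
                min_sites=1, min_spacing=250,
            )
            assert design.accepted_counts[cand.guide_id] == dp_max_spaced(sites, 250)


def _design_with_counts(counts):
    guides, tally = [], {}
    for i, n in enumerate(counts):
        proto = "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(20))
        cand = GuideCandidate(proto, ("c1", 17, "+"), n, n)
        guides.append(cand)
        tally[cand.guide_id] = n
    return GuideDesign(
        guides=guides, accepted_sites=CutSiteIndex([]), accepted_counts=tally
    )


def _design_distinct_counts(n_guides, start=10, step=7):
    guides, tally = [], {}
    rng = np.random.default_rng(99)
    seen = set()
    while len(guides) < n_guides:
        proto = random_seq(rng, 20)
        if proto in seen:
            continue
        seen.add(proto)
        n = start + step * len(guides)
        cand = GuideCandidate(proto, ("c1", 17, "+"), n, n)
        guides.append(cand)
        tally[cand.guide_id] = n
    return GuideDesign(
        guides=guides, accepted_sites=CutSiteIndex([]), accepted_counts=tally
    )


class TestPoolsAndGroups:
    def test_equal_split_preserves_frequency_order(self):
        design = _design_distinct_counts(22)
        assign_pools(design, n_pools=11)
        sizes = {}
        for gid, pool in design.pools.items():
            sizes[pool] = sizes.get(pool, 0) + 1
        assert sizes == {p: 2 for p in range(1, 12)}
        # pool numbers are nondecreasing in cutting frequency
        by_count = sorted(design.accepted_counts.items(), key=lambda kv: kv[1])
        pools_in_order = [design.pools[gid] for gid, _ in by_count]
        assert pools_in_order == sorted(pools_in_order)

    def test_ties_are_stable_and_balanced(self):
        design = _design_with_counts([5] * 23)
        assign_pools(design, n_pools=11)
        sizes = [0] * 12
        for pool in design.pools.values():
            sizes[pool] += 1
        occupied = [s for s in sizes[1:] if s]
        assert max(occupied) - min(occupied) <= 1
        again = _design_with_counts([5] * 23)
        assign_pools(again, n_pools=11)
        assert again.pools == design.pools

    def test_more_pools_than_guides(self):
        design = _design_distinct_counts(5)
        with pytest.warns(UserWarning, match="empty"):
            assign_pools(design, n_pools=11)
        assert sorted(set(design.pools.values())) == [1, 2, 3, 4, 5]

    def test_eleven_pools_three_groups_blocks(self):
        design = _design_distinct_counts(22)
        assign_pools(design, n_pools=11)
        group_for_sequential(design, n_groups=3)
        assert design.group_blocks == [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11]]

    def test_three_pools_three_groups(self):
        design = _design_distinct_counts(3)
        assign_pools(design, n_pools=3)
        group_for_sequential(design, n_groups=3)
        assert design.group_blocks == [[1], [2], [3]]

    def test_groups_ordered_by_cutting_frequency(self):
        design = _design_distinct_counts(33)
        assign_pools(design, n_pools=11)
        group_for_sequential(design, n_groups=3)
        freq_by_group = {}
        for gid, grp in design.groups.items():
            freq_by_group.setdefault(grp, []).append(design.accepted_counts[gid])
        for g in range(1, 3):
            assert max(freq_by_group[g]) < min(freq_by_group[g + 1])


class TestDosing:
    def test_proportional_split_620(self):
        design = _design_with_counts([100, 300])
        assign_pools(design, n_pools=2)
        plan = compute_dosing(design, total_ng=620)
        assert plan.per_pool_ng[1] == pytest.approx(155.0)
        assert plan.per_pool_ng[2] == pytest.approx(465.0)

    def test_cas9_volume_rule(self):
        design = _design_with_counts([10, 20, 30])
        plan = compute_dosing(design, total_ng=620)
        assert plan.cas9_ul == pytest.approx(0.0029 * 620)
        assert plan.cas9_ul == pytest.approx(1.798)

    def test_double_reaction(self):
        design = _design_with_counts([10, 20])
        plan = compute_dosing(design, total_ng=620, double=True)
        assert plan.total_ng == 1240.0
        assert plan.cas9_ul == pytest.approx(0.0029 * 1240)

    def test_mass_conservation(self, rng):
        counts = [int(c) for c in rng.integers(1, 500, size=40)]
        design = _design_with_counts(counts)
        plan = compute_dosing(design, total_ng=620)
        assert sum(plan.per_guide_ng.values()) == pytest.approx(620.0, rel=1e-9)

    def test_zero_sites_error(self):
        design = _design_with_counts([3])
        design.accepted_counts = {design.guides[0].guide_id: 0}
        with pytest.raises(ValueError, match="zero"):
            compute_dosing(design)


def _index_at(positions, contig="c1"):
    return CutSiteIndex([(contig, p, "+", "gX") for p in positions])


def footprint_oracle(cuts, length, insert):
    """Exhaustive fragment enumeration: a position is targetable iff
    every insert-length fragment covering it contains a cut."""
    n_targetable = 0
    for p in range(length):
        ok = True
        for a in range(max(0, p - insert + 1), min(p, length - insert) + 1):
            if not any(a <= c < a + insert for c in cuts):
                ok = False
                break
        if ok:
            n_targetable += 1
    return n_targetable


class TestTargetableFootprint:
    def _genome(self, length):
        return GenomeSequence({"c1": "A" * length})

    def test_small_gaps_fully_targetable(self):
        fp = targetable_footprint(_index_at([0, 400]), self._genome(401), 500)
        assert fp.targetable_bp == 401
        assert fp.nuclear_fraction == 1.0

    def test_large_gap_not_targetable(self):
        fp = targetable_footprint(_index_at([0, 1000]), self._genome(1001), 500)
        # only the two cut coordinates themselves are targetable
        assert fp.targetable_bp == 2

    def test_no_cut_sites_zero_footprint(self):
        fp = targetable_footprint(_index_at([]), self._genome(2000), 500)
        assert fp.targetable_bp == 0

    def test_matches_fragment_enumeration_oracle(self, rng):
        for _ in range(6):
            length = int(rng.integers(200, 800))
            insert = int(rng.integers(50, 250))
            n = int(rng.integers(0, 10))
            cuts = sorted(int(c) for c in rng.choice(length, n, replace=False))
            fp = targetable_footprint(_index_at(cuts), self._genome(length), insert)
            assert fp.targetable_bp == footprint_oracle(cuts, length, insert)

    def test_monotone_in_insert_size_and_sites(self, rng):
        length = 3000
        cuts = sorted(int(c) for c in rng.choice(length, 8, replace=False))
        genome = self._genome(length)
        fps = [
            targetable_footprint(_index_at(cuts), genome, i).targetable_bp
            for i in (100, 300, 600, 1200)
        ]
        assert fps == sorted(fps)
        more = sorted(set(cuts) | {150, 1750, 2500})
        assert (
            targetable_footprint(_index_at(more), genome, 300).targetable_bp
            >= targetable_footprint(_index_at(cuts), genome, 300).targetable_bp
        )

    def test_repeat_fraction(self):
        genome = GenomeSequence(
            {"c1": "A" * 1000, "chloroplast": "C" * 200}
        )
        repeats = AnnotationSet(
            [IntervalRecord("c1", 0, 400, "LTR_Gypsy")]
        ).merge()
        # cuts every 100 bp inside the repeat; nothing outside
        fp = targetable_footprint(
            _index_at(list(range(0, 401, 100))), genome, 150, repeats
        )
        assert fp.repeat_fraction == 1.0
        assert fp.targetable_bp < 1000
        # organelle contig excluded from the nuclear denominator
        assert fp.nuclear_fraction == fp.targetable_bp / 1000
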