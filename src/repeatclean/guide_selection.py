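"""Final guide-set selection, pooling, sequential grouping and dosing.

Selection is a deterministic greedy sweep: guides are visited in order
of decreasing cutting frequency (genome-wide on-target site count, ties
broken lexicographically by protospacer), and a guide is kept only if at
least ``min_sites`` of its cleavage sites can be accepted while keeping
every pair of accepted sites — across the whole design — at least
``min_spacing`` bp apart. Spacing between *accepted cleavage sites*
(rather than guide discovery positions) is what distributes cuts evenly
along the genome, which is the constraint's purpose: any 500-bp library
fragment inside the target space should contain a cut.

Guide mass is proportional to accepted cutting frequency, mirroring a
synthesis strategy in which each guide's copy number in the oligo pool
reflects its number of on-target cleavage sites.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    NUCLEAR,
    PROTECTED_CLASSES,
    AnnotationSet,
    GenomeSequence,
    intersect_pairs,
)
from .guide_discovery import CutSiteIndex, GuideCandidate
from .guide_filtering import FilterVerdict

logger = logging.getLogger(__name__)

DEFAULT_MIN_SITES = 25
DEFAULT_MIN_SPACING = 500
DEFAULT_N_POOLS = 11
DEFAULT_N_GROUPS = 3
DEFAULT_TOTAL_NG = 620.0
DEFAULT_CAS9_UL_PER_NG = 0.0029


@dataclass
class GuideDesign:
    """A selected guide set with accepted sites, pools, groups, dosing."""

    guides: list[GuideCandidate]
    accepted_sites: CutSiteIndex
    accepted_counts: dict[str, int]
    min_sites: int = DEFAULT_MIN_SITES
    min_spacing: int = DEFAULT_MIN_SPACING
    pools: dict[str, int] | None = None
    n_pools: int | None = None
    groups: dict[str, int] | None = None
    group_blocks: list[list[int]] | None = None
    nanograms: dict[str, float] | None = None
    total_ng: float | None = None
    cas9_ul: float | None = None

    def __len__(self) -> int:
        return len(self.guides)

    @property
    def is_empty(self) -> bool:
        return not self.guides

    def min_accepted_sites(self) -> int:
        """Smallest accepted-site count over selected guides."""
        if self.is_empty:
            raise ValueError("empty design")
        return min(self.accepted_counts.values())

    def min_intersite_gap(self) -> int:
        """Smallest gap between consecutive accepted sites on a contig."""
        gaps = []
        for contig in self.accepted_sites.contig_names():
            pos = self.accepted_sites.positions(contig)
            gaps.extend(b - a for a, b in zip(pos, pos[1:]))
        if not gaps:
            raise ValueError("fewer than two accepted sites on every contig")
        return min(gaps)


@dataclass
class DosingPlan:
    """Per-pool gRNA masses and the matching Cas9 volume."""

    per_pool_ng: dict[int, float]
    per_guide_ng: dict[str, float]
    total_ng: float
    cas9_ul: float
    ratio_note: str = "1:2.5 protein:gRNA"


def _spaced(positions: list[int], pos: int, min_spacing: int) -> bool:
    """True if ``pos`` keeps >= min_spacing from its sorted neighbours."""
    i = bisect_left(positions, pos)
    if i > 0 and pos - positions[i - 1] < min_spacing:
        return False
    if i < len(positions) and positions[i] - pos < min_spacing:
        return False
    return True


def select_guides(
    candidates: list[GuideCandidate],
    verdicts: list[FilterVerdict],
    index: CutSiteIndex,
    min_sites: int = DEFAULT_MIN_SITES,
    min_spacing: int = DEFAULT_MIN_SPACING,
) -> GuideDesign:
    """Greedy selection under the site-count and spacing constraints.

    Only guides whose verdict passed every filter are considered. For
    each guide (descending ``on_target_sites``, ties by protospacer) the
    sites compatible with all previously accepted sites are collected in
    coordinate order; the guide is accepted with exactly those sites if
    there are at least ``min_sites`` of them. An empty design (with a
    warning) is a valid output when no guide reaches the threshold.
    """
    passing = {v.guide_id for v in verdicts if v.overall_pass}
    order = sorted(
        (c for c in candidates if c.guide_id in passing and c.on_target_sites > 0),
        key=lambda c: (-c.on_target_sites, c.protospacer),
    )
    accepted: dict[str, list[int]] = {}
    sel_guides: list[GuideCandidate] = []
    sel_sites: list[tuple[str, int, str, str]] = []
    counts: dict[str, int] = {}
    for cand in order:
        tentative: list[tuple[str, int, str, str]] = []
        tent_pos: dict[str, list[int]] = {}
        for site in index.sites_for_guide(cand.guide_id):
            contig, pos = site[0], site[1]
            if _spaced(accepted.get(contig, []), pos, min_spacing) and _spaced(
                tent_pos.setdefault(contig, []), pos, min_spacing
            ):
                insort(tent_pos[contig], pos)
                tentative.append(site)
        if len(tentative) >= min_sites:
            for site in tentative:
                insort(accepted.setdefault(site[0], []), site[1])
            sel_sites.extend(tentative)
            counts[cand.guide_id] = len(tentative)
            sel_guides.append(cand)
    if not sel_guides:
        warnings.warn(
            "no guide satisfies the site-count/spacing constraints; "
            "returning an empty design",
            stacklevel=2,
        )
    return GuideDesign(
        guides=sel_guides,
        accepted_sites=CutSiteIndex(sel_sites),
        accepted_counts=counts,
        min_sites=min_sites,
        min_spacing=min_spacing,
    )


def assign_pools(design: GuideDesign, n_pools: int = DEFAULT_N_POOLS) -> GuideDesign:
    """Quantile-bin guides into pools by cutting frequency.

    Pool 1 holds the lowest-frequency guides; pool sizes differ by at
    most one. Ties are broken by protospacer so the binning is stable.
    When there are fewer guides than pools, the trailing pools stay
    empty (with a warning).
    """
    if design.is_empty:
        raise ValueError("cannot pool an empty design")
    ranked = sorted(
        design.guides,
        key=lambda c: (design.accepted_counts[c.guide_id], c.protospacer),
    )
    if n_pools > len(ranked):
        warnings.warn(
            f"{n_pools} pools requested for {len(ranked)} guides; "
            "trailing pools will be empty",
            stacklevel=2,
        )
    chunks = np.array_split(np.arange(len(ranked)), n_pools)
    pools: dict[str, int] = {}
    for pool_idx, chunk in enumerate(chunks, start=1):
        for i in chunk:
            pools[ranked[int(i)].guide_id] = pool_idx
    design.pools = pools
    design.n_pools = n_pools
    return design


def group_for_sequential(
    design: GuideDesign, n_groups: int = DEFAULT_N_GROUPS
) -> GuideDesign:
    """Partition pools into contiguous groups for sequential dosing.

    Groups are returned in increasing cutting-frequency order (group 1
    first = added first to the reaction); with 11 pools and 3 groups the
    default split is pools 1-4 / 5-8 / 9-11.
    """
    if design.pools is None or design.n_pools is None:
        raise ValueError("assign pools before grouping")
    blocks = [
        [int(p) for p in block]
        for block in np.array_split(np.arange(1, design.n_pools + 1), n_groups)
        if len(block)
    ]
    pool_to_group = {
        pool: gi for gi, block in enumerate(blocks, start=1) for pool in block
    }
    design.groups = {
        gid: pool_to_group[pool] for gid, pool in design.pools.items()
    }
    design.group_blocks = blocks
    return design


def compute_dosing(
    design: GuideDesign,
    total_ng: float = DEFAULT_TOTAL_NG,
    double: bool = False,
    cas9_ul_per_ng: float = DEFAULT_CAS9_UL_PER_NG,
) -> DosingPlan:
    """Split the total gRNA mass over guides proportionally to cutting
    frequency and derive the Cas9 volume.

    ``double=True`` doubles the reaction (1240 ng instead of 620 ng by
    default); the Cas9 volume is ``cas9_ul_per_ng * total``.
    """
    if design.is_empty:
        raise ValueError("cannot dose an empty design")
    total = 2.0 * total_ng if double else float(total_ng)
    counts = design.accepted_counts
    total_sites = sum(counts.values())
    if total_sites == 0:
        raise ValueError("design has zero accepted cleavage sites")
    per_guide = {
        gid: total * n / total_sites for gid, n in counts.items()
    }
    per_pool: dict[int, float] = {}
    if design.pools:
        for gid, ng in per_guide.items():
            pool = design.pools[gid]
            per_pool[pool] = per_pool.get(pool, 0.0) + ng
    else:
        per_pool[1] = total
    cas9_ul = cas9_ul_per_ng * total
    design.nanograms = per_guide
    design.total_ng = total
    design.cas9_ul = cas9_ul
    return DosingPlan(
        per_pool_ng=dict(sorted(per_pool.items())),
        per_guide_ng=per_guide,
        total_ng=total,
        cas9_ul=cas9_ul,
    )


# ---------------------------------------------------------------------------
# Targetable footprint
# ---------------------------------------------------------------------------


@dataclass
class FootprintResult:
    """Insert-size-aware footprint of a cut-site set."""

    targetable_bp: int
    nuclear_fraction: float
    repeat_fraction: float | None = None
    insert_size: int = DEFAULT_MIN_SPACING
    per_contig_bp: dict[str, int] = field(default_factory=dict)


def _dead_spans(
    cuts: list[int], length: int, insert_size: int
) -> list[tuple[int, int]]:
    """Maximal cut-free stretches of at least ``insert_size`` bp.

    A position inside such a stretch can sit on a fragment of the given
    insert length that avoids every cut; positions outside (including
    the cut coordinates themselves) cannot.
    """
    lefts = [0] + [c + 1 for c in cuts]
    rights = cuts + [length]
    return [(l, r) for l, r in zip(lefts, rights) if r - l >= insert_size]


def targetable_footprint(
    sites: CutSiteIndex,
    genome: GenomeSequence,
    insert_size: int = 500,
    repeats: AnnotationSet | None = None,
) -> FootprintResult:
    """Positions that no insert-sized fragment can cover cut-free.

    A position is *targetable* when every possible library fragment of
    ``insert_size`` bp covering it contains at least one cleavage site —
    equivalently, when the maximal cut-free gap containing the position
    is shorter than the insert. Fractions are reported over the nuclear
    genome and, when a repeat annotation is supplied, over the union of
    its non-protected classes.
    """
    per_contig: dict[str, int] = {}
    repeat_targetable = 0
    for contig in genome.contig_names(NUCLEAR):
        L = len(genome.contigs[contig])
        cuts = sites.positions(contig)
        dead = _dead_spans(cuts, L, insert_size)
        dead_bp = sum(e - s for s, e in dead)
        per_contig[contig] = L - dead_bp
        if repeats is not None:
            rep_pairs = repeats.contig_intervals(
                contig, classes=repeats.classes() - PROTECTED_CLASSES
            )
            rep_bp = sum(e - s for s, e in rep_pairs)
            dead_rep = sum(
                e - s for s, e in intersect_pairs(dead, rep_pairs)
            )
            repeat_targetable += rep_bp - dead_rep
    targetable_bp = sum(per_contig.values())
    nuclear_bp = genome.total_bp(NUCLEAR)
    repeat_fraction = None
    if repeats is not None:
        rep_total = repeats.total_bp(repeats.classes() - PROTECTED_CLASSES)
        repeat_fraction = repeat_targetable / rep_total if rep_total else None
    return FootprintResult(
        targetable_bp=targetable_bp,
        nuclear_fraction=targetable_bp / nuclear_bp,
        repeat_fraction=repeat_fraction,
        insert_size=insert_size,
        per_contig_bp=per_contig,
    )

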