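"""End-to-end guide design: scan, count, filter, select, pool, dose."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import AnnotationSet, GenomeSequence
from .guide_discovery import (
    CutSiteIndex,
    GuideCandidate,
    count_on_target_sites,
    scan_pam_sites,
)
from .guide_filtering import FilterConfig, FilterVerdict, apply_filters
from .guide_selection import (
    DEFAULT_MIN_SITES,
    DEFAULT_MIN_SPACING,
    DEFAULT_N_GROUPS,
    DEFAULT_N_POOLS,
    DEFAULT_TOTAL_NG,
    DosingPlan,
    FootprintResult,
    GuideDesign,
    assign_pools,
    compute_dosing,
    group_for_sequential,
    select_guides,
    targetable_footprint,
)

logger = logging.getLogger(__name__)


@dataclass
class DesignResult:
    """Everything a full design run produces."""

    candidates: list[GuideCandidate]
    verdicts: list[FilterVerdict]
    index: CutSiteIndex
    design: GuideDesign
    dosing: DosingPlan | None
    footprint: FootprintResult


def run_design(
    genome: GenomeSequence,
    repeats: AnnotationSet,
    protected: AnnotationSet,
    filter_config: FilterConfig | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
    min_spacing: int = DEFAULT_MIN_SPACING,
    n_pools: int = DEFAULT_N_POOLS,
    n_groups: int = DEFAULT_N_GROUPS,
    total_ng: float = DEFAULT_TOTAL_NG,
    double: bool = False,
    insert_size: int = 500,
) -> DesignResult:
    """Run the complete design pipeline with the standard defaults.

    Steps: merge the repeat annotation; enumerate candidate guides whose
    cut falls in a repeat interval; locate genome-wide exact matches and
    count on-target sites; apply sequence/efficiency/off-target filters
    against the protected regions; greedily select under the site-count
    and spacing constraints; assign pools, sequential groups and dosing;
    and compute the insert-size-aware targetable footprint.
    """
    repeats = repeats if repeats.merged else repeats.merge()
    candidates = scan_pam_sites(genome, repeats)
    logger.info("scanned %d candidate protospacers", len(candidates))
    index = count_on_target_sites(candidates, genome, repeats)
    candidates = [c for c in candidates if c.on_target_sites > 0]
    verdicts = apply_filters(candidates, genome, protected, filter_config)
    design = select_guides(candidates, verdicts, index, min_sites, min_spacing)
    dosing = None
    if not design.is_empty:
        assign_pools(design, n_pools)
        group_for_sequential(design, n_groups)
        dosing = compute_dosing(design, total_ng, double)
    footprint = targetable_footprint(
        design.accepted_sites, genome, insert_size, repeats
    )
    logger.info(
        "selected %d guides, %d accepted sites, %.1f%% nuclear footprint",
        len(design),
        len(design.accepted_sites),
        100.0 * footprint.nuclear_fraction,
    )
    return DesignResult(
        candidates=candidates,
        verdicts=verdicts,
        index=index,
        design=design,
        dosing=dosing,
        footprint=footprint,
    )
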