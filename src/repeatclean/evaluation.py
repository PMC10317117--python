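"""Depletion and genotyping metrics from placements and coverage.

All metrics operate on *placement tables* — one row per primary read
placement with columns ``contig, start, end, sample_id`` — so they work
identically on simulated placements and on placements ingested from a
SAM/BAM file (:func:`placements_from_sam`, which drops records carrying
any of the 2308 flag bits: unmapped, secondary, supplementary).

Class assignment uses the midpoint rule: a placement belongs to the
repeat class whose interval contains its midpoint; nuclear placements
whose midpoint falls in no repeat interval (including genes and open
chromatin) count as single copy, and organelle placements are classed
by compartment. Every placement gets exactly one class, so per-class
counts conserve the total.

Genotyping is summarised with a depth/allele model instead of a full
variant-calling pipeline: a position is *genotypable* (PASS) at depth
>= 5, and the probability of detecting a heterozygous variant at a
given depth follows binomial sampling of the alternate allele — the
allelic-imbalance mechanism by which low coverage silently drops
heterozygous calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import (
    NUCLEAR,
    PROTECTED_CLASSES,
    AnnotationSet,
    GenomeSequence,
)
from .guide_discovery import CutSiteIndex

logger = logging.getLogger(__name__)

SAM_EXCLUDE_FLAG = 2308  # unmapped | secondary | supplementary
SINGLE_COPY = "single_copy"
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_ALT_READS = 2
DEFAULT_DENSITY_THRESHOLD = 8.0


# ---------------------------------------------------------------------------
# Read counting by class
# ---------------------------------------------------------------------------


def _class_trees(
    annotation: AnnotationSet,
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in annotation:
        if r.class_label in PROTECTED_CLASSES:
            continue
        trees.setdefault(r.contig, IntervalTree()).addi(
            r.start, r.end, r.class_label
        )
    return trees


def count_by_class(
    placements: pd.DataFrame,
    annotation: AnnotationSet,
    genome: GenomeSequence,
) -> pd.DataFrame:
    """Midpoint-rule class counts per sample.

    Returns a tidy frame with columns ``sample_id, class_label, count``.
    Placements outside their contig bounds are an error. Overlapping
    records of different classes are resolved deterministically in
    favour of the earliest-starting (then lexicographically first)
    interval.
    """
    trees = _class_trees(annotation)
    lengths = genome.lengths
    labels = []
    for row in placements.itertuples(index=False):
        if row.contig not in lengths:
            raise ValueError(f"placement on unknown contig {row.contig!r}")
        if row.start < 0 or row.end > lengths[row.contig]:
            raise ValueError(
                f"placement [{row.start}, {row.end}) off contig {row.contig!r}"
            )
        comp = genome.compartment[row.contig]
        if comp != NUCLEAR:
            labels.append(comp)
            continue
        mid = (row.start + row.end) // 2
        hits = trees[row.contig][mid] if row.contig in trees else ()
        if hits:
            best = min(hits, key=lambda iv: (iv.begin, iv.end, iv.data))
            labels.append(best.data)
        else:
            labels.append(SINGLE_COPY)
    out = (
        placements.assign(class_label=labels)
        .groupby(["sample_id", "class_label"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out


@dataclass
class ReadCountSummary:
    """Primary-placement counts per (condition, sample, class)."""

    counts: pd.DataFrame  # condition, sample_id, class_label, count

    @classmethod
    def from_placements(
        cls,
        placements_by_condition: dict[str, pd.DataFrame],
        annotation: AnnotationSet,
        genome: GenomeSequence,
    ) -> "ReadCountSummary":
        frames = []
        for condition, placements in placements_by_condition.items():
            df = count_by_class(placements, annotation, genome)
            df.insert(0, "condition", condition)
            frames.append(df)
        return cls(pd.concat(frames, ignore_index=True))

    def class_totals(self, condition: str) -> pd.Series:
        """Counts per class summed over samples, plus derived totals.

        ``total_repeats`` sums every class except single copy (organelle
        classes included, as organelle genomes are depletion targets);
        ``nuclear_repeats`` excludes the organelle classes too.
        """
        sub = self.counts[self.counts.condition == condition]
        totals = sub.groupby("class_label")["count"].sum()
        organelle = {"chloroplast", "mitochondrial"}
        repeats = [
            c for c in totals.index if c != SINGLE_COPY and c not in organelle
        ]
        derived = {
            "total_repeats": totals.drop(SINGLE_COPY, errors="ignore").sum(),
            "nuclear_repeats": totals.loc[repeats].sum() if repeats else 0,
        }
        return pd.concat([totals, pd.Series(derived)]).astype(np.int64)

    def total(self, condition: str, class_label: str) -> int:
        return int(self.class_totals(condition).get(class_label, 0))


# ---------------------------------------------------------------------------
# Variation formulas
# ---------------------------------------------------------------------------


def variation_of_mapped_reads(depleted: float, nondepleted: float) -> float:
    """Signed relative change ``(depleted - nondepleted) / nondepleted``.

    A value of -0.40 is a 40% depletion; +1.60 is a 160% increase.
    Undefined (NaN) when the non-depleted count is zero.
    """
    if nondepleted == 0:
        return float("nan")
    return (depleted - nondepleted) / nondepleted


@dataclass
class ExclusionReport:
    """Bookkeeping for regions excluded from the log2 coverage ratio."""

    zero_depleted: int
    zero_nondepleted: int
    zero_both: int
    total: int

    @property
    def excluded(self) -> int:
        return self.zero_depleted + self.zero_nondepleted - self.zero_both

    @property
    def retained(self) -> int:
        return self.total - self.excluded

    @property
    def excluded_fraction(self) -> float:
        return self.excluded / self.total if self.total else float("nan")


def log2_coverage_variation(
    mean_depleted: np.ndarray, mean_nondepleted: np.ndarray
) -> tuple[np.ndarray, ExclusionReport]:
    """Per-region ``log2(mean_dep / mean_nondep)`` with exclusions.

    Regions with zero mean coverage in either condition are excluded
    (NaN in the returned array) and tallied in the report; excluded plus
    retained always equals the total.
    """
    dep = np.asarray(mean_depleted, dtype=float)
    nondep = np.asarray(mean_nondepleted, dtype=float)
    if dep.shape != nondep.shape:
        raise ValueError("coverage arrays must have identical shape")
    zd = dep == 0
    zn = nondep == 0
    values = np.full(dep.shape, np.nan)
    ok = ~zd & ~zn
    # difference of logs avoids overflow for extreme coverage ratios
    values[ok] = np.log2(dep[ok]) - np.log2(nondep[ok])
    report = ExclusionReport(
        zero_depleted=int(zd.sum()),
        zero_nondepleted=int(zn.sum()),
        zero_both=int((zd & zn).sum()),
        total=int(dep.size),
    )
    return values, report


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def position_depth(
    placements: pd.DataFrame, contig: str, length: int
) -> np.ndarray:
    """Per-base read depth on one contig (integer array of ``length``)."""
    sub = placements[placements.contig == contig]
    delta = np.zeros(length + 1, dtype=np.int64)
    np.add.at(delta, sub.start.to_numpy(), 1)
    np.add.at(delta, sub.end.to_numpy(), -1)
    return np.cumsum(delta[:-1])


@dataclass
class CoverageTrack:
    """Per-region mean coverage per condition plus per-base depth."""

    regions: pd.DataFrame  # contig, start, end, class_label, mean_<condition>...
    depth: dict[str, dict[str, np.ndarray]]  # condition -> contig -> depth

    @classmethod
    def from_placements(
        cls,
        placements_by_condition: dict[str, pd.DataFrame],
        regions: AnnotationSet | pd.DataFrame,
        genome: GenomeSequence,
    ) -> "CoverageTrack":
        rdf = (
            regions.to_dataframe()
            if isinstance(regions, AnnotationSet)
            else regions.copy()
        )
        depth: dict[str, dict[str, np.ndarray]] = {}
        for condition, placements in placements_by_condition.items():
            depth[condition] = {
                contig: position_depth(placements, contig, L)
                for contig, L in genome.lengths.items()
            }
            cums = {
                contig: np.concatenate(([0], np.cumsum(d)))
                for contig, d in depth[condition].items()
            }
            means = [
                (cums[r.contig][r.end] - cums[r.contig][r.start])
                / (r.end - r.start)
                for r in rdf.itertuples(index=False)
            ]
            rdf[f"mean_{condition}"] = means
        return cls(regions=rdf, depth=depth)

    def log2_variation(
        self, depleted: str = "depleted", nondepleted: str = "nondepleted"
    ) -> tuple[np.ndarray, ExclusionReport]:
        return log2_coverage_variation(
            self.regions[f"mean_{depleted}"].to_numpy(),
            self.regions[f"mean_{nondepleted}"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Genotypability
# ---------------------------------------------------------------------------


def genotypable_positions(
    depths: np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH
) -> int:
    """Number of positions with depth >= ``min_depth`` (PASS)."""
    return int(np.count_nonzero(np.asarray(depths) >= min_depth))


def pass_positions(
    depths: np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH
) -> np.ndarray:
    """Sorted coordinates of PASS positions."""
    return np.flatnonzero(np.asarray(depths) >= min_depth)


def common_genotyped_positions(position_sets) -> int:
    """Size of the intersection of per-sample PASS-position sets.

    Accepts sets or sorted coordinate arrays; at least two samples are
    required.
    """
    sets = list(position_sets)
    if len(sets) < 2:
        raise ValueError("need at least two samples to intersect")
    if all(isinstance(s, set) for s in sets):
        return len(set.intersection(*sets))
    arrays = [np.asarray(sorted(s)) if isinstance(s, set) else np.asarray(s) for s in sets]
    return int(reduce(np.intersect1d, arrays).size)


def het_detection_probability(
    depth: int,
    allele_fraction: float = 0.5,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float:
    """P(alternate reads >= min_alt_reads) at a heterozygous site.

    Alternate-allele reads at depth ``d`` follow
    ``Binomial(d, allele_fraction)``; a variant whose alternate support
    falls below ``min_alt_reads`` is missed (called reference). At
    depth 0 the probability is 0 for any positive threshold.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if min_alt_reads <= 0:
        return 1.0
    return float(stats.binom.sf(min_alt_reads - 1, depth, allele_fraction))


def expected_het_detection(
    depths: np.ndarray,
    allele_fraction: float = 0.5,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float:
    """Mean heterozygote-detection probability over a depth distribution."""
    depths = np.asarray(depths)
    return float(
        np.mean(stats.binom.sf(min_alt_reads - 1, depths, allele_fraction))
    )


def het_recovery_gain(
    depths_depleted: np.ndarray,
    depths_nondepleted: np.ndarray,
    allele_fraction: float = 0.5,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float:
    """Expected gain in heterozygote detection from depletion.

    Difference of the mean detection probabilities under the depleted
    and non-depleted depth distributions over the same positions.
    """
    return expected_het_detection(
        depths_depleted, allele_fraction, min_alt_reads
    ) - expected_het_detection(
        depths_nondepleted, allele_fraction, min_alt_reads
    )


# ---------------------------------------------------------------------------
# gRNA density vs depletion
# ---------------------------------------------------------------------------


def grna_density(
    regions: AnnotationSet | pd.DataFrame, sites: CutSiteIndex
) -> np.ndarray:
    """Cleavage sites per kbp for each region."""
    rdf = (
        regions.to_dataframe()
        if isinstance(regions, AnnotationSet)
        else regions
    )
    return np.array(
        [
            sites.count_in(r.contig, r.start, r.end) / ((r.end - r.start) / 1000.0)
            for r in rdf.itertuples(index=False)
        ]
    )


@dataclass
class DensityDepletionResult:
    correlation: float
    frac_reduced_above: float
    frac_reduced_below: float
    n_above: int
    n_below: int
    threshold: float


def density_vs_depletion(
    table: pd.DataFrame, threshold: float = DEFAULT_DENSITY_THRESHOLD
) -> DensityDepletionResult:
    """Relate gRNA density to coverage change across target regions.

    ``table`` needs columns ``density`` (cut sites per kbp) and
    ``log2_variation``; rows with NaN variation (excluded regions) are
    dropped first, and an all-excluded table is an error. Returns the
    Pearson correlation (NaN when either column is constant) and the
    fraction of regions showing a reduction (variation < 0) on each side
    of the density threshold.
    """
    df = table.dropna(subset=["density", "log2_variation"])
    if df.empty:
        raise ValueError("no regions left after exclusions")
    x = df["density"].to_numpy(dtype=float)
    y = df["log2_variation"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(x, y)[0])
    above = y[x > threshold]
    below = y[x <= threshold]
    return DensityDepletionResult(
        correlation=corr,
        frac_reduced_above=(
            float(np.mean(above < 0)) if above.size else float("nan")
        ),
        frac_reduced_below=(
            float(np.mean(below < 0)) if below.size else float("nan")
        ),
        n_above=int(above.size),
        n_below=int(below.size),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# SAM ingestion and the assembled report
# ---------------------------------------------------------------------------


def placements_from_sam(
    path: str, sample_id: str | None = None
) -> pd.DataFrame:
    """Primary-alignment placements from a SAM/BAM file.

    Records with any of the 2308 flag bits set (unmapped, secondary,
    supplementary) are discarded, so each sequenced fragment is counted
    once. The sample id comes from the read group tag when present.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.flag & SAM_EXCLUDE_FLAG:
                continue
            if read.reference_name is None or read.reference_end is None:
                continue
            sid = sample_id
            if sid is None:
                sid = read.get_tag("RG") if read.has_tag("RG") else "sample"
            rows.append(
                (read.reference_name, read.reference_start, read.reference_end, sid)
            )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "sample_id"]
    )


@dataclass
class DepletionReport:
    """Assembled depletion/genotyping metrics for one comparison."""

    summary: ReadCountSummary
    class_variation: pd.DataFrame  # class_label, depleted, nondepleted, variation
    exclusion: ExclusionReport | None
    genotypable: dict[str, int]
    min_depth: int


def depletion_report(
    placements_depleted: pd.DataFrame,
    placements_nondepleted: pd.DataFrame,
    annotation: AnnotationSet,
    genome: GenomeSequence,
    regions: AnnotationSet | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> DepletionReport:
    """Compute the standard report for a depleted/non-depleted pair.

    ``regions`` (default: the repeat annotation records themselves)
    defines the segments for the log2 coverage comparison. Genotypable
    positions are counted on single-copy nuclear positions — everything
    outside the repeat-class intervals.
    """
    conditions = {
        "depleted": placements_depleted,
        "nondepleted": placements_nondepleted,
    }
    summary = ReadCountSummary.from_placements(conditions, annotation, genome)
    dep_totals = summary.class_totals("depleted")
    nondep_totals = summary.class_totals("nondepleted")
    classes = sorted(set(dep_totals.index) | set(nondep_totals.index))
    class_variation = pd.DataFrame(
        {
            "class_label": classes,
            "depleted": [int(dep_totals.get(c, 0)) for c in classes],
            "nondepleted": [int(nondep_totals.get(c, 0)) for c in classes],
        }
    )
    class_variation["variation"] = [
        variation_of_mapped_reads(d, n)
        for d, n in zip(class_variation.depleted, class_variation.nondepleted)
    ]

    exclusion = None
    if regions is None:
        regions = annotation.subset(exclude=set(PROTECTED_CLASSES))
    if len(regions):
        track = CoverageTrack.from_placements(conditions, regions, genome)
        _, exclusion = track.log2_variation()

    genotypable = {}
    repeat_classes = annotation.classes() - PROTECTED_CLASSES
    for condition, placements in conditions.items():
        n_pass = 0
        for contig in genome.contig_names(NUCLEAR):
            L = genome.lengths[contig]
            depth = position_depth(placements, contig, L)
            mask = np.ones(L, dtype=bool)
            for s, e in annotation.contig_intervals(contig, repeat_classes):
                mask[s:e] = False
            n_pass += genotypable_positions(depth[mask], min_depth)
        genotypable[condition] = n_pass

    return DepletionReport(
        summary=summary,
        class_variation=class_variation,
        exclusion=exclusion,
        genotypable=genotypable,
        min_depth=min_depth,
    )
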