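"""Sequence-quality filters and mismatch-tolerant off-target exclusion.

Candidate guides pass a cascade of filters before selection:

1. sequence composition — GC content window, homopolymer runs,
   dinucleotide repeats, self-complementary hairpin stems;
2. predicted cleavage efficiency — a pluggable scorer (the default is a
   transparent position-weight heuristic, see
   :func:`default_efficiency_score`);
3. off-target exclusion — a guide is discarded outright if any site in
   the protected regions (genes and ATAC open chromatin) matches it
   within ``offtarget_max_mismatches`` Hamming mismatches.

The off-target search uses a pigeonhole seed index: the 20-mer is split
into ``max_mm + 1`` contiguous chunks, so any hit within ``max_mm``
mismatches must match at least one chunk exactly. Chunk lookups produce
a small candidate set that is then verified by full Hamming distance;
the result is exactly the naive brute-force scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import AnnotationSet, GenomeSequence, reverse_complement
from .guide_discovery import CUT_OFFSET, GuideCandidate

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class FilterConfig:
    """Thresholds for the filter cascade.

    Sequence thresholds are inclusive pass bounds: a guide fails when
    its GC fraction falls outside ``[gc_min, gc_max]``, its longest
    homopolymer exceeds ``max_homopolymer``, its longest dinucleotide
    tandem exceeds ``max_dinucleotide_repeat`` units, its longest
    hairpin stem reaches ``max_hairpin_stem``, or its efficiency score
    falls below ``efficiency_min``.

    ``pam_free_offtarget`` drops the requirement for an adjacent NGG at
    off-target sites — a stricter reading in which mere sequence
    complementarity inside a protected region disqualifies a guide.
    """

    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 4
    max_dinucleotide_repeat: int = 4
    max_hairpin_stem: int = 6
    efficiency_min: float = 0.2
    offtarget_max_mismatches: int = 3
    pam_free_offtarget: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min < self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.offtarget_max_mismatches < 0:
            raise ValueError("offtarget_max_mismatches must be >= 0")


@dataclass
class FilterVerdict:
    """Per-guide filter outcome with every computed flag."""

    guide_id: str
    protospacer: str
    gc: float
    gc_pass: bool
    homopolymer: int
    homopolymer_pass: bool
    dinucleotide_units: int
    dinucleotide_pass: bool
    hairpin: int
    hairpin_pass: bool
    efficiency_score: float
    efficiency_pass: bool
    efficiency_flagged: bool = False
    offtarget_hits: int | None = None

    @property
    def sequence_pass(self) -> bool:
        return (
            self.gc_pass
            and self.homopolymer_pass
            and self.dinucleotide_pass
            and self.hairpin_pass
            and self.efficiency_pass
        )

    @property
    def overall_pass(self) -> bool:
        return self.sequence_pass and self.offtarget_hits == 0


# ---------------------------------------------------------------------------
# Sequence filters
# ---------------------------------------------------------------------------


def gc_content(protospacer: str) -> float:
    """Fraction of G+C bases in a 20-nt protospacer."""
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    return (protospacer.count("G") + protospacer.count("C")) / 20.0


def max_run_filters(protospacer: str) -> tuple[int, int]:
    """Return (longest homopolymer run, longest dinucleotide tandem).

    The dinucleotide value is the maximal number of consecutive
    repetitions of any 2-mer with two *distinct* bases (``ATATAT`` has
    three units); same-base 2-mers are the homopolymer filter's job.
    """
    n = len(protospacer)
    homo = 1
    run = 1
    for i in range(1, n):
        run = run + 1 if protospacer[i] == protospacer[i - 1] else 1
        homo = max(homo, run)
    dinuc = 0
    for i in range(n - 1):
        unit = protospacer[i : i + 2]
        if unit[0] == unit[1]:
            continue
        count = 1
        j = i + 2
        while j + 2 <= n and protospacer[j : j + 2] == unit:
            count += 1
            j += 2
        dinuc = max(dinuc, count)
    return homo, dinuc


def hairpin_stem(protospacer: str) -> int:
    """Longest self-complementary stem a 20-mer can fold into.

    Returns the largest ``k`` for which two substrings ``s1`` (ending
    before ``s2`` starts) and ``s2``, separated by a loop of at least
    3 nt, satisfy ``s2 == reverse_complement(s1)``.
    """
    n = len(protospacer)
    best = 0
    for k in range((n - 3) // 2, 0, -1):
        found = False
        for i in range(0, n - 2 * k - 3 + 1):
            rc = reverse_complement(protospacer[i : i + k])
            for j in range(i + k + 3, n - k + 1):
                if protospacer[j : j + k] == rc:
                    found = True
                    break
            if found:
                break
        if found:
            best = k
            break
    return best


# ---------------------------------------------------------------------------
# Efficiency scoring
# ---------------------------------------------------------------------------


def extract_context(
    genome: GenomeSequence, site: tuple[str, int, str]
) -> str | None:
    """30-nt scoring context at a discovery site, 5'->3' on the
    protospacer strand: 4 nt upstream + protospacer + PAM + 3 nt
    downstream. Returns ``None`` when truncated at a contig edge.
    """
    contig, cut, strand = site
    seq = genome.contigs[contig]
    if strand == "+":
        i = cut - CUT_OFFSET
        if i - 4 < 0 or i + 26 > len(seq):
            return None
        return seq[i - 4 : i + 26]
    p = cut - 6
    if p - 3 < 0 or p + 27 > len(seq):
        return None
    return reverse_complement(seq[p - 3 : p + 27])


def default_efficiency_score(protospacer: str, context: str | None = None) -> float:
    """Deterministic position-weight heuristic on ``[0.15, 1.0]``.

    Rewards a GC fraction near 0.5 and a G at protospacer position 20
    (the PAM-proximal base, empirically favourable for SpCas9), and
    penalises a T there (unfavourable, and a U tract can terminate
    pol-III transcription). The 30-nt context is accepted for interface
    compatibility with trained scorers but not used by the heuristic.

    Changing the position-20 base from T to G never decreases the score.
    """
    gc = gc_content(protospacer)
    gc_term = 1.0 - 2.0 * abs(gc - 0.5)
    last = protospacer[19]
    pos20 = {"G": 1.0, "T": 0.0}.get(last, 0.5)
    return round(0.15 + 0.55 * gc_term + 0.30 * pos20, 6)


NEUTRAL_EFFICIENCY = 0.5


# ---------------------------------------------------------------------------
# Off-target search
# ---------------------------------------------------------------------------


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


class OffTargetIndex:
    """Pigeonhole-seeded index of protected-region protospacer windows.

    A window is any genomic 20-mer (on either strand) whose site
    overlaps a protected interval by at least one base — conservatively,
    the full 23-mer including the PAM when a PAM is required. With
    ``pam_free=True`` the PAM requirement is dropped and windows are
    bare 20-mers.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        protected: AnnotationSet,
        max_mm: int = 3,
        pam_free: bool = False,
    ):
        self.max_mm = max_mm
        if not protected.merged:
            protected = protected.merge()
        span = 20 if pam_free else 23
        keys: set[tuple[str, int, str]] = set()
        for contig in protected.contig_names():
            if contig not in genome:
                continue
            L = len(genome.contigs[contig])
            for s, e in protected.contig_intervals(contig):
                lo = max(0, s - (span - 1))
                hi = min(L - span, e - 1)
                for i in range(lo, hi + 1):
                    keys.add((contig, i, "+"))
                    keys.add((contig, i, "-"))
        windows: list[str] = []
        for contig, i, strand in sorted(keys):
            seq = genome.contigs[contig]
            if pam_free:
                w = seq[i : i + 20]
                if strand == "-":
                    w = reverse_complement(w)
            elif strand == "+":
                if seq[i + 21 : i + 23] != "GG" or seq[i + 20] not in _ACGT:
                    continue
                w = seq[i : i + 20]
            else:
                if seq[i : i + 2] != "CC" or seq[i + 2] not in _ACGT:
                    continue
                w = reverse_complement(seq[i + 3 : i + 23])
            if set(w) - _ACGT:
                continue
            windows.append(w)
        self.windows = windows
        bounds = np.linspace(0, 20, max_mm + 2).astype(int)
        self.chunks = [
            (int(bounds[i]), int(bounds[i + 1])) for i in range(max_mm + 1)
        ]
        self._seed: dict[tuple[int, str], list[int]] = {}
        for wi, w in enumerate(windows):
            for ci, (a, b) in enumerate(self.chunks):
                self._seed.setdefault((ci, w[a:b]), []).append(wi)

    def hits(self, protospacer: str) -> int:
        cand: set[int] = set()
        for ci, (a, b) in enumerate(self.chunks):
            cand.update(self._seed.get((ci, protospacer[a:b]), ()))
        return sum(
            1
            for wi in cand
            if _hamming_at_most(protospacer, self.windows[wi], self.max_mm)
        )


def offtarget_hits(
    protospacer: str,
    genome: GenomeSequence,
    protected: AnnotationSet,
    max_mm: int = 3,
    pam_free: bool = False,
    index: OffTargetIndex | None = None,
) -> int:
    """Count protected-region sites within ``max_mm`` mismatches.

    Builds a throwaway :class:`OffTargetIndex` unless one is supplied;
    batch callers should build the index once.
    """
    if index is None:
        index = OffTargetIndex(genome, protected, max_mm, pam_free)
    return index.hits(protospacer)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def apply_filters(
    candidates: list[GuideCandidate],
    genome: GenomeSequence,
    protected: AnnotationSet,
    cfg: FilterConfig | None = None,
    scorer=None,
) -> list[FilterVerdict]:
    """Run the full cascade: sequence filters first, then off-target.

    The off-target search is skipped (``offtarget_hits=None``) for
    guides that already failed a sequence filter; all sequence flags are
    recorded regardless. The surviving set is order-independent: it is
    the intersection of the individual filters' survivor sets.
    """
    cfg = cfg or FilterConfig()
    scorer = scorer or default_efficiency_score
    index = OffTargetIndex(
        genome, protected, cfg.offtarget_max_mismatches, cfg.pam_free_offtarget
    )
    verdicts = []
    n_skipped = 0
    for cand in candidates:
        p = cand.protospacer
        gc = gc_content(p)
        homo, dinuc = max_run_filters(p)
        stem = hairpin_stem(p)
        context = extract_context(genome, cand.discovery_site)
        if context is None:
            score, flagged = NEUTRAL_EFFICIENCY, True
        else:
            score, flagged = float(scorer(p, context)), False
        v = FilterVerdict(
            guide_id=cand.guide_id,
            protospacer=p,
            gc=gc,
            gc_pass=cfg.gc_min <= gc <= cfg.gc_max,
            homopolymer=homo,
            homopolymer_pass=homo <= cfg.max_homopolymer,
            dinucleotide_units=dinuc,
            dinucleotide_pass=dinuc <= cfg.max_dinucleotide_repeat,
            hairpin=stem,
            hairpin_pass=stem < cfg.max_hairpin_stem,
            efficiency_score=score,
            efficiency_pass=score >= cfg.efficiency_min,
            efficiency_flagged=flagged,
        )
        if v.sequence_pass:
            v.offtarget_hits = index.hits(p)
        else:
            n_skipped += 1
        verdicts.append(v)
    if n_skipped:
        logger.info(
            "off-target search skipped for %d guides failing sequence filters",
            n_skipped,
        )
    return verdicts
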