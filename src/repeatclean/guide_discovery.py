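"""Candidate guide enumeration and genome-wide cleavage-site counting.

SpCas9 recognises a 20-nt protospacer followed immediately by an NGG
PAM and leaves a blunt double-strand break 3 bp 5' of the PAM, between
protospacer positions 17 and 18. In the package's half-open coordinates
a plus-strand site with protospacer ``[i, i+20)`` and PAM ``[i+20, i+23)``
therefore cuts at boundary coordinate ``i + 17``; the mirror-image
minus-strand site (``CCN`` at ``[p, p+3)``, protospacer ``[p+3, p+23)``
on the reverse strand) cuts at ``p + 6``.

Candidates are deduplicated by protospacer sequence: a synthesised gRNA
is one molecule regardless of how many genomic sites it matches, so one
:class:`GuideCandidate` represents every exact occurrence of a 20-mer.
"""

from __future__ import annotations

import hashlib
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator

from .genome_io import AnnotationSet, GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
#: distance from the protospacer 5' end to the blunt-cut boundary
CUT_OFFSET = 17

_ACGT = frozenset("ACGT")


def guide_id_for(protospacer: str) -> str:
    """Stable, content-derived guide identifier."""
    return "g" + hashlib.sha1(protospacer.encode("ascii")).hexdigest()[:12]


@dataclass
class GuideCandidate:
    """A distinct 20-nt protospacer with its discovery site and site counts.

    ``protospacer`` is always written 5'->3' as the gRNA spacer would be
    synthesised: the genome-strand sequence for plus-strand sites, the
    reverse complement for minus-strand sites. ``on_target_sites`` counts
    genome-wide exact protospacer+NGG matches whose cut coordinate falls
    inside a target interval; ``total_sites`` counts all exact matches,
    on-target or not.
    """

    protospacer: str
    discovery_site: tuple[str, int, str]
    on_target_sites: int = 0
    total_sites: int = 0
    guide_id: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be exactly 20 nt")
        if set(self.protospacer) - _ACGT:
            raise ValueError("protospacer must be A/C/G/T only")
        if not self.guide_id:
            self.guide_id = guide_id_for(self.protospacer)


class CutSiteIndex:
    """All cleavage sites of a guide set, sorted and interval-queryable.

    Each site is a ``(contig, cut_position, strand, guide_id)`` tuple,
    sorted by ``(contig, cut_position)``.
    """

    def __init__(self, sites: list[tuple[str, int, str, str]]):
        self.sites = sorted(sites)
        self._positions: dict[str, list[int]] = {}
        self._by_guide: dict[str, list[tuple[str, int, str, str]]] = {}
        for site in self.sites:
            self._by_guide.setdefault(site[3], []).append(site)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def contig_names(self) -> list[str]:
        return sorted({s[0] for s in self.sites})

    def positions(self, contig: str) -> list[int]:
        """Sorted, deduplicated cut coordinates on one contig."""
        if contig not in self._positions:
            self._positions[contig] = sorted(
                {s[1] for s in self.sites if s[0] == contig}
            )
        return self._positions[contig]

    def sites_for_guide(self, guide_id: str) -> list[tuple[str, int, str, str]]:
        return list(self._by_guide.get(guide_id, []))

    def count_in(self, contig: str, start: int, end: int) -> int:
        """Number of distinct cut positions with ``start <= c < end``."""
        pos = self.positions(contig)
        return bisect_right(pos, end - 1) - bisect_right(pos, start - 1)


def _scan_region(
    seq: str, start: int, end: int
) -> Iterator[tuple[int, str, str]]:
    """Yield ``(cut_position, strand, protospacer)`` for every NGG site
    whose cut coordinate falls in ``[start, end)``.

    Windows containing N (in the protospacer or the PAM) are skipped.
    """
    L = len(seq)
    # plus strand: protospacer [i, i+20), PAM [i+20, i+23), cut i+17
    for i in range(max(0, start - CUT_OFFSET), min(L - 23, end - CUT_OFFSET - 1) + 1):
        if seq[i + 21 : i + 23] == "GG" and seq[i + 20] in _ACGT:
            proto = seq[i : i + 20]
            if not set(proto) - _ACGT:
                yield i + CUT_OFFSET, "+", proto
    # minus strand: CCN at [p, p+3), protospacer [p+3, p+23), cut p+6
    for p in range(max(0, start - 6), min(L - 23, end - 7) + 1):
        if seq[p : p + 2] == "CC" and seq[p + 2] in _ACGT:
            proto_genome = seq[p + 3 : p + 23]
            if not set(proto_genome) - _ACGT:
                yield p + 6, "-", reverse_complement(proto_genome)


def scan_pam_sites(
    genome: GenomeSequence, targets: AnnotationSet
) -> list[GuideCandidate]:
    """Enumerate every distinct protospacer whose cut falls in a target.

    Both strands are scanned; a candidate is recorded at its first
    discovery site (contig order, then coordinate). Target intervals on
    contigs absent from the genome are skipped with a warning.
    """
    if not targets.merged:
        targets = targets.merge()
    unknown = set(targets.contig_names()) - set(genome.contigs)
    for contig in sorted(unknown):
        logger.warning("target interval on unknown contig %r skipped", contig)
    seen: dict[str, GuideCandidate] = {}
    for contig, seq in genome.contigs.items():
        for s, e in targets.contig_intervals(contig):
            for cut, strand, proto in _scan_region(seq, s, e):
                if proto not in seen:
                    seen[proto] = GuideCandidate(proto, (contig, cut, strand))
    return list(seen.values())


def _interval_lookup(targets: AnnotationSet, contig: str):
    pairs = targets.contig_intervals(contig)
    starts = [s for s, _ in pairs]
    ends = [e for _, e in pairs]
    return starts, ends


def _in_intervals(starts: list[int], ends: list[int], pos: int) -> bool:
    idx = bisect_right(starts, pos) - 1
    return idx >= 0 and pos < ends[idx]


def count_on_target_sites(
    candidates: list[GuideCandidate],
    genome: GenomeSequence,
    targets: AnnotationSet,
) -> CutSiteIndex:
    """Locate all genome-wide exact matches of each candidate.

    Matches whose cut coordinate lies in a target interval enter the
    returned :class:`CutSiteIndex` and increment ``on_target_sites``;
    every exact match increments ``total_sites``. Counts are reset
    before the scan, so the operation is idempotent. Candidates left
    with ``on_target_sites == 0`` are simply absent from the index and
    should be dropped by the caller.
    """
    if not targets.merged:
        targets = targets.merge()
    by_proto = {c.protospacer: c for c in candidates}
    for c in candidates:
        c.on_target_sites = 0
        c.total_sites = 0
    sites: list[tuple[str, int, str, str]] = []
    for contig, seq in genome.contigs.items():
        starts, ends = _interval_lookup(targets, contig)
        for cut, strand, proto in _scan_region(seq, 0, len(seq)):
            cand = by_proto.get(proto)
            if cand is None:
                continue
            cand.total_sites += 1
            if _in_intervals(starts, ends, cut):
                cand.on_target_sites += 1
                sites.append((contig, cut, strand, cand.guide_id))
    return CutSiteIndex(sites)
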