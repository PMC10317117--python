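"""File I/O and the package-wide coordinate conventions.

Every interval handled by this package is 0-based and half-open,
``[start, end)`` — the BED convention. GFF3 input (1-based, fully closed)
is converted once, at the parsing boundary, and never re-exposed.

Cas9 cleavage sites are *boundary* coordinates in the same system: a cut
at coordinate ``c`` severs any library fragment ``[start, end)`` with
``start <= c < end``. All downstream modules (selection spacing,
targetable footprint, depletion simulation) share this single rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEAR = "nuclear"
CHLOROPLAST = "chloroplast"
MITOCHONDRIAL = "mitochondrial"

#: Annotation classes that are protected from targeting (genes and
#: ATAC-seq open chromatin). Reads falling in them count as single copy.
PROTECTED_CLASSES = frozenset({"gene", "atac_peak"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})
_VALID_BASES = frozenset("ACGTN")

GUIDE_TABLE_COLUMNS = [
    "guide_id",
    "protospacer",
    "on_target_sites",
    "pool",
    "group",
    "nanograms",
]

PLACEMENT_COLUMNS = ["contig", "start", "end", "sample_id"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome sequences
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A genome as uppercase A/C/G/T/N strings, one per contig.

    Parameters
    ----------
    contigs
        Ordered mapping of contig name to sequence. Insertion order is
        the genome order.
    compartment
        Per-contig label: ``nuclear``, ``chloroplast`` or
        ``mitochondrial``. Missing entries default to nuclear.
    softmask
        Optional per-contig boolean arrays marking bases that were
        lowercase (soft-masked) in the source FASTA. Soft-masking is
        recorded but deliberately ignored by the design modules: targets
        come from explicit annotation intervals only.
    """

    contigs: dict[str, str]
    compartment: dict[str, str] = field(default_factory=dict)
    softmask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
        for name in self.contigs:
            self.compartment.setdefault(name, _infer_compartment(name))

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def contig_names(self, compartment: str | None = None) -> list[str]:
        if compartment is None:
            return list(self.contigs)
        return [n for n in self.contigs if self.compartment[n] == compartment]

    def total_bp(self, compartment: str | None = None) -> int:
        return sum(len(self.contigs[n]) for n in self.contig_names(compartment))


def _infer_compartment(name: str) -> str:
    low = name.lower()
    if "chloroplast" in low or "plastid" in low or low == "cpdna":
        return CHLOROPLAST
    if "mitochond" in low or low == "mtdna":
        return MITOCHONDRIAL
    return NUCLEAR


def _clean_sequence(raw: str, name: str) -> tuple[str, np.ndarray]:
    codes = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
    soft = (codes >= 97) & (codes <= 122)
    seq = raw.upper().translate(_IUPAC_TO_N)
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq, soft


def read_fasta(
    path: str | Path, compartments: dict[str, str] | None = None
) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; lowercase (soft-masked) stretches are kept
    as a parallel boolean mask. IUPAC ambiguity codes become ``N``.
    Contig order follows the file. Duplicate contig names and empty
    records are hard errors.

    ``compartments`` overrides the name-based organelle inference
    (contig names containing "chloroplast" / "mitochondrion" are
    auto-labelled).
    """
    contigs: dict[str, str] = {}
    comp: dict[str, str] = {}
    soft: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        raw = str(record.seq)
        if not raw:
            raise ValueError(f"empty FASTA record {record.id!r} in {path}")
        seq, mask = _clean_sequence(raw, record.id)
        contigs[record.id] = seq
        if mask.any():
            soft[record.id] = mask
        override = (compartments or {}).get(record.id)
        comp[record.id] = override or _infer_compartment(record.id)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs, comp, soft)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class IntervalRecord:
    """A classified genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    class_label: str = "region"
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse overlapping or abutting ``(start, end)`` pairs."""
    out: list[list[int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect_pairs(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted, disjoint half-open interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass
class AnnotationSet:
    """A collection of :class:`IntervalRecord` with merge bookkeeping."""

    records: list[IntervalRecord]
    merged: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def classes(self) -> set[str]:
        return {r.class_label for r in self.records}

    def contig_names(self) -> list[str]:
        return sorted({r.contig for r in self.records})

    def subset(
        self,
        classes: set[str] | None = None,
        exclude: set[str] | None = None,
    ) -> "AnnotationSet":
        recs = [
            r
            for r in self.records
            if (classes is None or r.class_label in classes)
            and (exclude is None or r.class_label not in exclude)
        ]
        return AnnotationSet(recs, merged=self.merged)

    def merge(self) -> "AnnotationSet":
        """Collapse overlapping/abutting same-class records.

        Idempotent; merged records on mixed strands get strand ``.``.
        """
        grouped: dict[tuple[str, str], list[IntervalRecord]] = {}
        for r in self.records:
            grouped.setdefault((r.contig, r.class_label), []).append(r)
        out: list[IntervalRecord] = []
        for (contig, label), recs in grouped.items():
            recs.sort(key=lambda r: (r.start, r.end))
            cur_s, cur_e = recs[0].start, recs[0].end
            strands = {recs[0].strand}
            for r in recs[1:]:
                if r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                    strands.add(r.strand)
                else:
                    out.append(
                        IntervalRecord(
                            contig, cur_s, cur_e, label,
                            strands.pop() if len(strands) == 1 else ".",
                        )
                    )
                    cur_s, cur_e, strands = r.start, r.end, {r.strand}
            out.append(
                IntervalRecord(
                    contig, cur_s, cur_e, label,
                    strands.pop() if len(strands) == 1 else ".",
                )
            )
        out.sort(key=lambda r: (r.contig, r.start, r.end, r.class_label))
        return AnnotationSet(out, merged=True)

    def contig_intervals(
        self, contig: str, classes: set[str] | None = None
    ) -> list[tuple[int, int]]:
        """Merged union of intervals (across classes) on one contig."""
        pairs = [
            (r.start, r.end)
            for r in self.records
            if r.contig == contig
            and (classes is None or r.class_label in classes)
        ]
        return merge_pairs(pairs)

    def total_bp(self, classes: set[str] | None = None) -> int:
        """Total bp covered by the union of (selected) intervals."""
        return sum(
            e - s
            for contig in self.contig_names()
            for s, e in self.contig_intervals(contig, classes)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.contig, r.start, r.end, r.class_label, r.strand)
                for r in self.records
            ],
            columns=["contig", "start", "end", "class_label", "strand"],
        )


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_intervals(
    path: str | Path,
    dialect: str = "bed",
    class_from: str | None = None,
    genome: GenomeSequence | None = None,
    unknown_contig: str = "keep",
) -> AnnotationSet:
    """Read BED (0-based half-open) or GFF3 (converted on read) intervals.

    Parameters
    ----------
    dialect
        ``"bed"`` or ``"gff"``.
    class_from
        For GFF3, the attribute key that carries the class label; the
        feature *type* column is used when omitted. BED takes column 4.
    genome, unknown_contig
        When a genome is supplied, records on contigs absent from it are
        handled per ``unknown_contig``: ``"keep"``, ``"reject"`` (drop
        with a warning) or ``"error"``.

    Records that are empty after coordinate conversion are rejected with
    a logged warning rather than failing the whole file.
    """
    path = Path(path)
    if dialect not in ("bed", "gff"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return AnnotationSet([])

    records: list[IntervalRecord] = []
    for row in df.itertuples(index=False):
        if dialect == "bed":
            contig = str(row[0])
            start, end = int(row[1]), int(row[2])
            label = str(row[3]) if len(row) > 3 and pd.notna(row[3]) else "region"
            strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
        else:
            contig = str(row[0])
            label = str(row[2])
            start, end = int(row[3]) - 1, int(row[4])
            if class_from is not None:
                attrs = _parse_gff_attributes(str(row[8])) if len(row) > 8 else {}
                label = attrs.get(class_from, label)
            strand = str(row[6]) if len(row) > 6 and str(row[6]) in "+-" else "."
        if start >= end or start < 0:
            logger.warning(
                "rejecting interval %s:[%d,%d) in %s (empty after conversion)",
                contig, start, end, path,
            )
            continue
        if genome is not None and contig not in genome:
            if unknown_contig == "error":
                raise ValueError(f"unknown contig {contig!r} in {path}")
            if unknown_contig == "reject":
                logger.warning("dropping record on unknown contig %r", contig)
                continue
        records.append(IntervalRecord(contig, start, end, label, strand))
    return AnnotationSet(records)


def write_intervals(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an annotation set as BED4 (BED6 when any strand is set)."""
    stranded = any(r.strand != "." for r in annotation)
    with open(path, "w") as fh:
        for r in annotation:
            if stranded:
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\t{r.class_label}\t0\t{r.strand}\n"
                )
            else:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.class_label}\n")


# ---------------------------------------------------------------------------
# Guide tables and placement tables
# ---------------------------------------------------------------------------


def write_guides(design, path: str | Path, bed_path: str | Path | None = None):
    """Write a guide design as a TSV table plus a cut-site BED track.

    The table has one row per selected guide (columns
    :data:`GUIDE_TABLE_COLUMNS`); the BED has one single-base feature
    per accepted cleavage site, with the guide's accepted-site count in
    the score column. An empty design produces a header-only table and
    an empty BED.
    """
    path = Path(path)
    if bed_path is None:
        bed_path = path.with_name(path.stem + ".sites.bed")
    rows = []
    for cand in design.guides:
        gid = cand.guide_id
        rows.append(
            {
                "guide_id": gid,
                "protospacer": cand.protospacer,
                "on_target_sites": design.accepted_counts.get(gid, 0),
                "pool": design.pools.get(gid) if design.pools else pd.NA,
                "group": design.groups.get(gid) if design.groups else pd.NA,
                "nanograms": design.nanograms.get(gid) if design.nanograms else pd.NA,
            }
        )
    df = pd.DataFrame(rows, columns=GUIDE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for contig, cut, strand, gid in design.accepted_sites.sites:
            score = design.accepted_counts.get(gid, 0)
            fh.write(f"{contig}\t{cut}\t{cut + 1}\t{gid}\t{score}\t{strand}\n")


def read_guides(path: str | Path) -> pd.DataFrame:
    """Read a guide table written by :func:`write_guides`."""
    return pd.read_csv(path, sep="\t", dtype={"guide_id": str, "protospacer": str})


def write_placements(placements: pd.DataFrame, path: str | Path) -> None:
    """Write a placement table as BED4 (column 4 = sample id)."""
    placements[PLACEMENT_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_placements(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=PLACEMENT_COLUMNS,
            dtype={"contig": str, "sample_id": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=PLACEMENT_COLUMNS)
    return df
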