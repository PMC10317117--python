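"""Synthetic genomes, library simulation and in-silico Cas9 depletion.

The generator plants what the depletion method assumes about a large
plant genome, scaled to desk size: diverged copies of a few repeat
family consensuses (LTR retrotransposon-like families dominating, minor
families at higher divergence), protein-coding genes and open-chromatin
intervals that repeats must not overlap, and high-copy organelle
contigs. Organelle over-representation is modelled by per-contig
sampling weights rather than literal multi-copy sequence — identical
read-level behaviour at a fraction of the memory.

Depletion follows the adapter-loss mechanism: a Cas9 cut anywhere
inside a library fragment removes one adapter, so the fragment cannot
amplify. Each contained cleavage site is treated as an independent
Bernoulli cut with probability ``p_cut``; fragment survival is the
product of per-site escape probabilities. A density-boost hook lets the
effective per-site probability grow with local gRNA density, emulating
the empirically observed density dependence of depletion efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .genome_io import (
    CHLOROPLAST,
    MITOCHONDRIAL,
    AnnotationSet,
    GenomeSequence,
    IntervalRecord,
)
from .guide_discovery import CutSiteIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatFamily:
    """A planted repeat family: diverged copies of one consensus."""

    class_label: str
    consensus_length: int
    copies: int
    divergence: float  # per-base substitution probability per copy


@dataclass(frozen=True)
class Organelle:
    name: str
    length: int
    weight: float  # per-base sampling weight relative to nuclear DNA


@dataclass
class SyntheticGenomeSpec:
    """Composition of a synthetic genome with ground-truth labels.

    The defaults describe a 200-kb nuclear chromosome in which LTR
    retrotransposon-like families dominate the repeat fraction (the
    Gypsy-like family largest, then Copia-like, then a smaller and more
    diverged LINE-like family; ~58% repeats in total), plus genes (10%)
    and ATAC open-chromatin peaks that repeats may not overlap, and two
    organelle contigs whose sampling weights put organelle reads near
    ~1% of a whole-genome library, dominated by the chloroplast.
    """

    nuclear_length: int = 200_000
    nuclear_contig: str = "chr1"
    families: tuple[RepeatFamily, ...] = (
        RepeatFamily("LTR_Gypsy", 600, 100, 0.02),
        RepeatFamily("LTR_Copia", 450, 70, 0.03),
        RepeatFamily("LINE", 500, 50, 0.05),
    )
    n_genes: int = 20
    gene_length: int = 1000
    n_open_chromatin: int = 25
    open_chromatin_length: int = 300
    organelles: tuple[Organelle, ...] = (
        Organelle("chloroplast", 6_000, 0.40),
        Organelle("mitochondrion", 12_000, 0.03),
    )
    seed: int = 42

    def contig_weights(self) -> dict[str, float]:
        w = {self.nuclear_contig: 1.0}
        w.update({o.name: o.weight for o in self.organelles})
        return w

    def with_seed(self, seed: int) -> "SyntheticGenomeSpec":
        return replace(self, seed=seed)

    def planted_bp(self) -> int:
        return (
            sum(f.consensus_length * f.copies for f in self.families)
            + self.n_genes * self.gene_length
            + self.n_open_chromatin * self.open_chromatin_length
        )


@dataclass(slots=True)
class LibraryFragment:
    """One adapter-ligated library molecule (half-open placement)."""

    contig: str
    start: int
    end: int
    sample_id: str
    survived: bool | None = None


@dataclass
class CutModel:
    """Per-site cut probability with an optional density boost.

    ``density_boost`` maps a fragment's local gRNA density (cut sites
    per kbp of fragment) to a multiplier on ``p_cut``; the effective
    probability is clipped to 1.
    """

    p_cut: float
    density_boost: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cut <= 1.0:
            raise ValueError("p_cut must be in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    """Base-index array (0..3) of length n."""
    return rng.integers(0, 4, n, dtype=np.uint8)


def _to_string(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(
    codes: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. substitutions: each base flips to a different base."""
    out = codes.copy()
    hit = rng.random(len(codes)) < divergence
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out


_RC_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


class _Allocator:
    """Uniform-ish placement of non-overlapping features on [0, L)."""

    def __init__(self, length: int):
        self.free: list[tuple[int, int]] = [(0, length)]

    def place(self, length: int, rng: np.random.Generator) -> int:
        fits = [(s, e) for s, e in self.free if e - s >= length]
        if not fits:
            raise ValueError(
                "requested features exceed the available genome length"
            )
        weights = np.array([e - s - length + 1 for s, e in fits], dtype=float)
        seg = fits[int(rng.choice(len(fits), p=weights / weights.sum()))]
        start = seg[0] + int(rng.integers(0, seg[1] - seg[0] - length + 1))
        self.free.remove(seg)
        if start > seg[0]:
            self.free.append((seg[0], start))
        if start + length < seg[1]:
            self.free.append((start + length, seg[1]))
        return start


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[GenomeSequence, AnnotationSet]:
    """Generate a labelled synthetic genome, deterministic given the seed.

    Genes and open-chromatin intervals are placed first, then repeat
    copies, all mutually non-overlapping; each repeat copy is the family
    consensus with i.i.d. substitutions at the family divergence rate,
    inserted in a random orientation. The returned annotation carries
    every planted feature as ground truth.
    """
    if spec.planted_bp() > spec.nuclear_length:
        raise ValueError("requested features exceed genome length")
    rng = np.random.default_rng(spec.seed)
    codes = _random_bases(rng, spec.nuclear_length)
    alloc = _Allocator(spec.nuclear_length)
    records: list[IntervalRecord] = []

    for _ in range(spec.n_genes):
        s = alloc.place(spec.gene_length, rng)
        records.append(
            IntervalRecord(spec.nuclear_contig, s, s + spec.gene_length, "gene")
        )
    for _ in range(spec.n_open_chromatin):
        s = alloc.place(spec.open_chromatin_length, rng)
        records.append(
            IntervalRecord(
                spec.nuclear_contig, s, s + spec.open_chromatin_length,
                "atac_peak",
            )
        )
    for fam in spec.families:
        consensus = _random_bases(rng, fam.consensus_length)
        for _ in range(fam.copies):
            s = alloc.place(fam.consensus_length, rng)
            copy = _mutate(consensus, fam.divergence, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy = _RC_CODE[copy][::-1]
            codes[s : s + fam.consensus_length] = copy
            records.append(
                IntervalRecord(
                    spec.nuclear_contig, s, s + fam.consensus_length,
                    fam.class_label, strand,
                )
            )

    contigs = {spec.nuclear_contig: _to_string(codes)}
    compartment = {spec.nuclear_contig: "nuclear"}
    for org in spec.organelles:
        contigs[org.name] = _to_string(_random_bases(rng, org.length))
        compartment[org.name] = (
            CHLOROPLAST if "chloro" in org.name else MITOCHONDRIAL
        )
    records.sort(key=lambda r: (r.contig, r.start, r.end))
    return GenomeSequence(contigs, compartment), AnnotationSet(records)


def simulate_library(
    genome: GenomeSequence,
    n_fragments: int,
    n_samples: int = 8,
    insert_mean: int = 500,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    insert_sd: float | None = None,
    min_length: int = 100,
    max_length: int | None = None,
) -> list[LibraryFragment]:
    """Draw random-primed library fragments from a genome.

    Fragment origins are uniform over the genome weighted per contig by
    ``length x weight`` (organelle over-representation); lengths come
    from a normal distribution (mean ``insert_mean``, sd 0.15x mean by
    default) truncated to ``[min_length, 2 x insert_mean]`` and to the
    contig. Sample ids ``S1..Sn`` are assigned round-robin, emulating a
    multiplex library in which every sample is drawn from the same
    genome.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    sd = insert_sd if insert_sd is not None else 0.15 * insert_mean
    max_len = max_length if max_length is not None else 2 * insert_mean
    names = list(genome.contigs)
    lens = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    w = np.array([(weights or {}).get(n, 1.0) for n in names]) * lens
    if w.sum() <= 0:
        raise ValueError("all contig weights are zero")
    contig_idx = rng.choice(len(names), n_fragments, p=w / w.sum())
    lengths = np.clip(
        np.rint(rng.normal(insert_mean, sd, n_fragments)), min_length, max_len
    ).astype(np.int64)
    lengths = np.minimum(lengths, lens[contig_idx].astype(np.int64))
    starts = np.floor(
        rng.random(n_fragments) * (lens[contig_idx] - lengths + 1)
    ).astype(np.int64)
    sample_ids = [f"S{i % n_samples + 1}" for i in range(n_fragments)]
    return [
        LibraryFragment(names[ci], int(s), int(s + l), sid)
        for ci, s, l, sid in zip(contig_idx, starts, lengths, sample_ids)
    ]


def apply_depletion(
    fragments: list[LibraryFragment],
    sites: CutSiteIndex,
    model: CutModel,
    seed: int = 0,
) -> list[LibraryFragment]:
    """Sample each fragment's survival after Cas9 treatment (in place).

    A fragment containing ``n`` distinct cleavage sites survives with
    probability ``(1 - p_eff)^n``; with ``p_cut = 1`` survival is
    exactly "contains no site".
    """
    rng = np.random.default_rng(seed)
    pos_cache: dict[str, np.ndarray] = {}
    for frag in fragments:
        pos = pos_cache.get(frag.contig)
        if pos is None:
            pos = np.asarray(sites.positions(frag.contig), dtype=np.int64)
            pos_cache[frag.contig] = pos
        n = int(
            np.searchsorted(pos, frag.end, side="left")
            - np.searchsorted(pos, frag.start, side="left")
        )
        if n == 0:
            frag.survived = True
            continue
        p_eff = model.p_cut
        if model.density_boost is not None:
            density = n / ((frag.end - frag.start) / 1000.0)
            p_eff = min(1.0, p_eff * model.density_boost(density))
        survival = (1.0 - p_eff) ** n
        frag.survived = bool(rng.random() < survival)
    return fragments


def sample_reads(
    fragments: list[LibraryFragment],
    n_reads: int,
    condition: str = "depleted",
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform with-replacement sample of read placements.

    ``condition="depleted"`` samples only surviving fragments;
    ``"nondepleted"`` samples all fragments. Sampling both conditions at
    the same ``n_reads`` normalises them to the same sequencing input.
    """
    if condition not in ("depleted", "nondepleted"):
        raise ValueError(f"unknown condition {condition!r}")
    pool = (
        [f for f in fragments if f.survived]
        if condition == "depleted"
        else list(fragments)
    )
    if not pool:
        raise ValueError("no fragments available to sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), n_reads)
    return pd.DataFrame(
        {
            "contig": [pool[i].contig for i in idx],
            "start": np.array([pool[i].start for i in idx], dtype=np.int64),
            "end": np.array([pool[i].end for i in idx], dtype=np.int64),
            "sample_id": [pool[i].sample_id for i in idx],
        }
    )


def downsample_placements(
    placements: pd.DataFrame, n: int, seed: int = 0
) -> pd.DataFrame:
    """Without-replacement downsampling to ``n`` placements."""
    if n > len(placements):
        raise ValueError("cannot downsample beyond the table size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(placements), n, replace=False)
    return placements.iloc[np.sort(idx)].reset_index(drop=True)
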