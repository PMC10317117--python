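# repeatclean

CRISPR-Cas9 guide design, in-silico depletion and evaluation for
repeat-rich sequencing libraries.

In species whose genomes are dominated by repetitive DNA — many crop
plants exceed 80% repeat content — most whole-genome sequencing reads
land on transposable elements and other repeats that are largely
uninformative for genotyping. Cas9 ribonucleoproteins programmed with a
large pool of repeat-targeting gRNAs can cut library fragments derived
from repeats; a cut fragment loses one adapter and cannot amplify, so
sequencing concentrates on the single-copy (genic and regulatory)
fraction instead. `repeatclean` implements the computational side of
this strategy for anyone designing such a gRNA set or studying its
expected effect: guide discovery and filtering, dosage-balanced pool
layout, a depletion simulator, and the evaluation metrics used to
quantify depletion and genotyping gains.

## The method

**Design.** All 20-nt protospacers with an adjacent SpCas9 PAM (5'-NGG)
are enumerated on both strands of the repeat annotation; the blunt cut
falls 3 bp 5' of the PAM. Candidates are filtered for GC content,
homopolymers, dinucleotide repeats, hairpin stems and predicted
cleavage efficiency (pluggable scorer), and any guide with a site
within 3 mismatches (Hamming, PAM-adjacent) inside *protected* regions
— genes and ATAC-seq open chromatin — is discarded. From the survivors
a greedy sweep (descending cutting frequency) selects guides with at
least **25 on-target cleavage sites** each while keeping every pair of
accepted sites at least **500 bp** apart. Selected guides are
quantile-binned into 11 pools by cutting frequency, the pools split
into 3 groups used sequentially in order of increasing frequency, and
the gRNA mass (620 ng per reaction, 1240 ng for a double reaction)
split over guides in proportion to their cleavage-site counts, with
0.0029 µL Cas9 per ng gRNA (1:2.5 protein:gRNA).

**Simulation.** A synthetic-genome generator plants diverged repeat
families, genes, open chromatin and weighted organelle contigs;
a library simulator draws insert-sized fragments; depletion treats each
cleavage site in a fragment as an independent Bernoulli cut with
probability `p_cut`, so a fragment containing `n` sites survives with
probability `(1 − p_cut)^n`.

**Evaluation.** Per-class read counts use the midpoint rule on primary
placements. Depletion is quantified as

    variation = (reads_depleted − reads_nondepleted) / reads_nondepleted
    log2 coverage variation = log2(cov_depleted / cov_nondepleted)

(regions with zero coverage in either condition are excluded and
tallied). Genotypability counts positions at depth ≥ 5 (PASS), and
heterozygote detection is modelled as `P(alt reads ≥ k)` under
`Binomial(depth, allele fraction)` — the allelic-imbalance mechanism
that silently drops heterozygous calls at low coverage.

## Worked example

```python
from repeatclean import SyntheticGenomeSpec, generate_genome, run_design
from repeatclean.genome_io import PROTECTED_CLASSES

spec = SyntheticGenomeSpec().with_seed(42)     # 200-kb labelled genome
genome, truth = generate_genome(spec)
repeats = truth.subset(exclude=set(PROTECTED_CLASSES))
protected = truth.subset(classes=set(PROTECTED_CLASSES))

result = run_design(genome, repeats, protected)
design = result.design
for cand in design.guides:
    print(cand.guide_id, cand.protospacer,
          design.accepted_counts[cand.guide_id],
          design.pools[cand.guide_id], design.groups[cand.guide_id])
print("min sites", design.min_accepted_sites(),
      "min gap", design.min_intersite_gap(),
      "Cas9 uL", round(design.cas9_ul, 3))
```

prints

```
g24754c5db231 TTGTGGGCTCCAATTTTAGC 76 2 1
g5488bc9c4d77 CGAAGCTGATATATCGCACA 38 1 1
min sites 38 min gap 511 Cas9 uL 1.798
```

Two guides pass every filter and constraint on this small genome: one
hits 76 accepted sites in the Gypsy-like family, the other 38 in the
Copia-like family. Every guide has ≥ 25 accepted sites, no two accepted
sites are closer than 500 bp, and the 620-ng gRNA mass implies 1.798 µL
of Cas9. With a global 500-bp spacing constraint and 500-bp inserts the
targetable footprint of the *selected* set is essentially the cut
positions themselves (see `docs/methods.md`); footprints of denser site
sets are computed with `targetable_footprint`.

The same pipeline is available from the shell:

```sh
repeatclean design run --genome genome.fa --targets repeats.bed \
    --protected genes_atac.bed --out guides.tsv
repeatclean simulate --out-prefix sim --reads 100000 --seed 7
repeatclean evaluate --depleted dep.bed --nondepleted nondep.bed \
    --annotation truth.bed --genome genome.fa
```

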