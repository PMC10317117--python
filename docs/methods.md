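# Methods

## Coordinate and cleavage conventions

All intervals are 0-based half-open (`[start, end)`); GFF3 input is
converted at the parsing boundary. A cleavage site is a boundary
coordinate: the SpCas9 blunt cut lies between protospacer positions 17
and 18, i.e. 3 bp 5' of the NGG PAM, so a plus-strand site with
protospacer `[i, i+20)` cuts at `i + 17` and a minus-strand site (CCN
at `[p, p+3)`) cuts at `p + 6`. A fragment `[start, end)` is severed by
a cut `c` when `start <= c < end`. Selection spacing, the targetable
footprint and the depletion simulator all use this one rule, which is
what makes the closure tests exact.

Candidate guides are deduplicated by protospacer sequence: one
synthesised gRNA species corresponds to one 20-mer, however many
genomic sites it matches. "In the target intervals" is interpreted as
the *cut coordinate* falling inside an interval, because cutting is
what destroys a fragment; a protospacer may straddle an interval edge.
Soft-masked (lowercase) genome sequence is recorded but never treated
as a target: targets come exclusively from explicit annotation
intervals. Windows containing N are skipped — a guide cannot be
validated against ambiguous sequence.

## Filter cascade

Defaults (all configurable through `FilterConfig`):

| parameter | default | fails when |
| --- | --- | --- |
| GC fraction | 0.25–0.75 | outside the closed interval |
| homopolymer | 4 | any single-base run ≥ 5 |
| dinucleotide tandem | 4 units | any 2-mer repeated ≥ 5 times |
| hairpin stem | 6 | a self-complementary stem of ≥ 6 bp with a ≥ 3-nt loop |
| efficiency score | ≥ 0.2 | heuristic score below threshold |
| off-target mismatches | 3 | any PAM-adjacent site within 3 mismatches of a protected region |

These sequence thresholds are design choices typical of published gRNA
design practice, not reconstructions of any specific pipeline; the
monotonicity property (tightening a threshold never grows the survivor
set, verified by test) makes downstream behaviour robust to their exact
values.

Efficiency scoring is a pluggable interface. Trained regression
scorers can be swapped in via the `scorer` argument of
`apply_filters`; the default is a transparent position-weight
heuristic, `0.15 + 0.55·(1 − 2|GC − 0.5|) + 0.30·w(base20)` with
`w(G)=1, w(A/C)=0.5, w(T)=0`, reflecting two robust empirical
regularities (intermediate GC is favourable; a PAM-proximal G helps, a
terminal T/U hurts). Its range is [0.15, 1.0], it is deterministic and
monotone under T→G at position 20, and at the default threshold it
only excludes compositional extremes — the filter becomes selective
when users raise `efficiency_min` or plug in a trained model. Sites
whose 30-nt scoring context (4 nt + protospacer + PAM + 3 nt) is
truncated by a contig edge receive a neutral 0.5 and are flagged.

Off-target exclusion requires a functional NGG next to the
near-complementary site, matching Cas9 biochemistry; the stricter
PAM-free reading (any complementarity disqualifies) is available via
`pam_free_offtarget`. Interval membership for off-target sites uses
any overlap of the full 23-mer with a protected interval —
conservative protection of functional regions. The search uses a
pigeonhole seed index (split the 20-mer into `max_mm + 1` chunks; any
hit within `max_mm` mismatches matches one chunk exactly; verify
candidates by Hamming distance), which is exactly equivalent to the
naive scan — the test suite proves equivalence exhaustively on a 50-kb
genome.

## Selection, pooling, dosing

The constraints (≥ 25 cleavage sites per guide, ≥ 500 bp between
accepted sites) are given; the algorithm satisfying them is a package
decision, chosen to be deterministic and seed-free: visit guides by
descending genome-wide on-target count (ties lexicographic by
protospacer); within a guide, sweep its sites in coordinate order,
accepting each site that keeps ≥ 500 bp from all previously accepted
sites (the left-to-right greedy yields a maximum spaced subset, which
is verified against a dynamic program); commit the guide only if ≥ 25
sites survive. Spacing is enforced *globally* across guides: the
constraint's purpose is an even genome-wide cut distribution, and the
constraint metrics reported by `scripts/acceptance.py` (minimum
accepted-site count, minimum inter-site distance) are defined on that
reading. A consequence worth stating: with spacing ≥ 500 and 500-bp
inserts, inter-cut gaps admit a cut-free 500-bp fragment except when
the gap is exactly 500, so the footprint of a *selected* set reduces
to roughly its cut positions. The footprint operation is therefore
most informative on denser site sets (e.g. the full candidate index
before selection), and the tests exercise it there.

Pooling ranks selected guides by *accepted* cutting frequency and
quantile-bins them into 11 pools (pool 1 = lowest frequency, sizes
within 1 of each other, ties broken by protospacer); pools are split
into 3 contiguous blocks (4/4/3 for 11 pools) used sequentially in
increasing-frequency order. Dosing distributes the total gRNA mass
(620 ng, or 1240 ng for the double reaction) over guides proportionally
to accepted site count — emulating oligo pools in which a guide's copy
number reflects its target count — and the Cas9 volume is
0.0029 µL per ng of gRNA (a 1:2.5 protein:gRNA ratio). Accepted counts
(not raw genome-wide counts) drive pooling and dosing because they are
the sites the design actually credits; raw counts only order the
greedy sweep.

The targetable footprint formalises "targetable with I-bp inserts" as:
position `p` is targetable iff every fragment of length `I` covering
`p` contains ≥ 1 cut — equivalently the maximal cut-free stretch
containing `p` is shorter than `I`. Cut coordinates themselves are
always targetable. The implementation reduces to gap arithmetic and is
tested against exhaustive fragment enumeration.

## Synthetic genomes — what they emulate, and what not

`SyntheticGenomeSpec` defaults define the desk-scale study conditions
used throughout the tests and the acceptance script (chosen once, for
realism at 1/20,000 of a large plant genome):

* one 200-kb nuclear contig;
* three repeat families with 50–100 copies at 2–5% per-base divergence
  from a random consensus — an LTR/Gypsy-like family (600 bp × 100 ×
  2%), an LTR/Copia-like family (450 bp × 70 × 3%) and a LINE-like
  family (500 bp × 50 × 5%), ~58% of the contig, mirroring the
  LTR-dominated composition of large legume genomes;
* 20 genes of 1 kb (10%) and 25 open-chromatin peaks of 300 bp,
  placed first; repeats never overlap them (repeats overlapping
  functional regions are excluded from targeting by construction);
* chloroplast (6 kb) and mitochondrial (12 kb) contigs whose sampling
  weights (0.40 and 0.03 per bp) put organelle reads near ~1.2% of a
  library, dominated by the chloroplast — organelle over-representation
  is modelled by weights, not literal multi-copy sequence, which gives
  identical read-level behaviour at a fraction of the memory.

Repeat copies carry i.i.d. substitutions; each copy is inserted in a
random orientation. Divergence controls how many copies a single guide
can still match exactly (a 20-mer survives a copy with probability
`(1 − d)^20`), which is what makes the ≥ 25-site constraint
family-selective: at 2% divergence a consensus window is intact in
~67 of 100 copies, at 5% in ~18 of 50 — so high-divergence families
drop out of the design exactly as poorly conserved repeat classes
resist depletion in practice.

Not emulated: nested/fragmented repeat insertions, GC and PCR bias,
mapping error (placements are ground truth), sequence-level reads.
Passing tests therefore demonstrate the correctness of the design and
evaluation machinery under the stated model, not mapping-robustness on
real reads.

## Depletion model

Each cleavage site inside a fragment is an independent Bernoulli cut
with probability `p_cut`; survival is `(1 − p_eff)^n` over the `n`
distinct cut coordinates contained. No cooperative cutting is modelled
— the simplest model consistent with the adapter-loss mechanism — but
a `density_boost` hook lets the effective per-site probability grow
with local site density (sites per kbp of fragment), so users can
emulate the empirically observed density dependence (regions above
~8 sites/kbp depleting far more reliably). Library fragments are
normal-length (mean 500 bp, sd 15%, truncated to [100, 1000] bp),
uniform over contigs weighted by length × weight, with round-robin
sample ids emulating a multiplex library. Sampling reads at a fixed
`n_reads` in both conditions normalises them to the same sequencing
input.

Closure properties verified by the acceptance tests: with `p_cut = 1`
and intra-repeat cut gaps far below the minimum fragment length, the
repeat-read variation reaches −1 and single-copy reads strictly
increase; `p_cut` is recovered from single-site fragment survival
within Monte-Carlo error.

## Evaluation choices

* **Midpoint rule** for class assignment: every placement gets exactly
  one class, so counts conserve the total. Gene/open-chromatin hits
  count as single copy (nuclear non-target DNA), organelle contigs are
  classed by compartment; `total_repeats` includes organelles (they
  are depletion targets), `nuclear_repeats` does not.
* **Zero-coverage exclusion** for the log2 ratio: regions with zero
  mean coverage in either condition are excluded and reported
  (zero-in-depleted, zero-in-nondepleted, zero-in-both; excluded
  fraction `(zd + zn − zb)/total`). The log2 is computed as a
  difference of logs to avoid overflow at extreme ratios.
* **Genotyping model**: variant calling is deliberately replaced by a
  depth/allele model — PASS at depth ≥ 5, heterozygote detection
  `P(alt ≥ k)` under `Binomial(depth, af)` with `k = 2` by default.
  This captures the allelic-imbalance mechanism without an external
  caller; SAM/BAM ingestion (primary placements only, flag 2308
  excluded) feeds real alignments into the same metrics.
* **Density relation**: Pearson correlation between per-region site
  density and log2 variation, plus the fraction of regions reduced on
  either side of the 8 sites/kbp threshold; the correlation is
  reported as missing for degenerate (constant) inputs.

## Numerical and degenerate-input conventions

Ties everywhere break lexicographically by protospacer, making every
pipeline stage deterministic without seeds. Merging annotations is
idempotent and same-class only. An empty design is a valid selection
outcome (warning, not error); pooling/dosing an empty design is an
error, as is dosing a zero-site design or sampling from zero surviving
fragments. `variation_of_mapped_reads` with a zero baseline is
reported as missing (NaN). Dosing masses sum to the requested total to
floating-point accuracy. All stochastic operations take explicit seeds
and are reproducible bit-for-bit.

## Problem sizes

Defaults were sized for interactive use: the full design pipeline on
the 200-kb default genome runs in about a second; simulation closure
uses 10^5 fragments/reads; the exhaustive oracle comparisons use a
50-kb genome (off-target), 10-kb contigs (PAM scan) and 4-kb contigs
(footprint enumeration).

## Known limitations

* Only the NGG PAM is scanned (no NAG, no bulge-tolerant off-targets);
  off-target counting is Hamming-based.
* The default efficiency heuristic is intentionally simple; quantitative
  efficiency claims require plugging in a trained scorer.
* The global spacing constraint cannot reproduce the dense site sets a
  per-guide spacing reading would give at genome scale (see Selection
  above); at desk scale the two readings select similar top guides.
* RNA-folding thermodynamics, synthesis-chemistry constraints and
  optimal (set-cover) selection are out of scope.
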