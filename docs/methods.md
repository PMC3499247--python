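# Methods

This note documents the models, defaults and numerical choices behind
`snapcall`, and what the synthetic benchmark does and does not establish.

## Tag model

A tag is a collapsed mapped read: interval, strand, `times_sequenced` (the
number of identical reads collapsed onto it) and `n_matches` (genome-wide
perfect-match count).  Inclusion rules: tags aligning with any mismatch are
excluded (optionally retained for ELAND-style comparisons), as are tags
with more than 500 genomic matches.  Every retained tag carries the weight

```
w = min(1, times_sequenced / n_matches)
```

applied per reported placement.  Whether the original analyses placed a
multi-tag at every match or at one is not recoverable from published
descriptions; placing the capped weight at each reported placement keeps a
tag's total influence ≤ its read count and is recorded in the retention
report metadata.  Unique tags (`n_matches = 1`) contribute their full
`times_sequenced` to occupancy scores; multi-tags contribute `w` per
placement.  Coordinates are 0-based half-open throughout; GFF3 is converted
on input/output.

## Peak caller

A strand-transition caller in the SISSRs family, reconstructed from the
published description of that approach rather than from any binary, and
generalized to weighted counts so repeated gene families stay callable.

* Net count `c(i)` = windowed (default `window_w` = 20 bp, centered) sense
  minus antisense weighted 5′-end counts.
* Candidate summits: sign transitions of `c` from + to −; a zero plateau at
  the transition yields its midpoint (deterministic and symmetric).
* Peak extent: `[summit − L_f, summit + L_f)` with `L_f` = fragment length
  (default 150 bp; the simulator's fragment-end model shifts 5′ ends by
  `L_f/2`, so 100 sense tags ending 75 bp upstream and 100 antisense
  starting 75 bp downstream reconstruct the planted site).
* Candidates closer than `L_f` are chain-merged; the maximum-support
  transition represents the group.
* Support threshold: the smallest `k` with `Pr[Poisson(λ) ≥ k] ≤ FDR`,
  where `λ = total_weight × window / genome_length`.  Because support is
  evaluated over the peak extent (2`L_f`) while candidates arise at
  `window_w` resolution, the extent overlaps `2L_f / window_w` scanning
  windows and the effective FDR inside `call_peaks` is Bonferroni-corrected
  by that factor; `estimate_min_tag_count` itself implements the exact
  uncorrected Poisson tail semantics.  Weighted support is rounded up
  before comparison.  Default FDR 0.001% (1e-5).

On 100 pure-background simulations (1 Mb, 10⁵ tags) the caller produces
zero false peaks, well inside the binomial budget per scanning window.

## SNAPc bin methods

The genome is tiled into 200-nt bins; a tag belongs to the bin containing
its 5′ end.  Two calling methods, both requiring ≥ 2 of the four assayed
subunits per positive bin:

* **threshold** — subunit positive when its weighted count reaches the
  Poisson minimum tag count with the bin size as the window (bins tile
  without overlap, so no multiplicity correction applies).
* **normal_bh** — per subunit, a normal distribution is fitted (method of
  moments, population variance) over the *occupied* bins (count > 0); each
  tested bin receives the one-sided upper-tail p-value, BH-adjusted over
  all tested bins of that subunit genome-wide, positive at adjusted
  p < 0.005.  Empty bins dominate a genome and are not treated as data;
  `fit_include_zeros` (with an explicit genome bin count) restores the
  alternative reading.  A degenerate fit (σ = 0) calls nothing and warns.
  BH pooling is per subunit, not per chromosome — one global null per
  antibody.

On the benchmark the normal_bh positives are a strict subset of the
threshold positives and both methods mark every planted promoter; they
disagree only on secondary flank bins, because at toy scale the planted
signal is ~2% of occupied bins and inflates the fitted σ (at genome scale
that fraction is negligible).

## Locus assembly

A locus = polymerase peak (POLR2B or POLR3D) + basal peak (GTF2B or BRF2)
with interval gap ≤ 100 bp + SNAPc-positive bin with gap ≤ 100 nt of the
polymerase peak.  Gap distance (0 when overlapping, boundary inclusive) is
the default because it is robust to peak width; summit-to-summit mode is
available.  Candidates on the same route with overlapping extents merge
into one locus: the polymerase termination zone can generate secondary
downstream polymerase peaks of the same promoter, and the procedure selects
genomic *regions*.  The two routes are assembled independently; a
dual-polymerase promoter appears in both and the route lists are collapsed
by overlap into a single locus table.

Manual curation is replaced by flags: `low_unique_fraction` when the pooled
unique fraction of the polymerase+basal scores is < 15%,
`ambiguous_unique_fraction` between 15% and 20%, and `high_background` when
≥ 6 unrelated factors show peaks with identical boundaries inside the
locus.

## Scoring and classification

Occupancy scores separate a unique component (Σ `times_sequenced` of
unique-match tags overlapping the region) from a multi component
(Σ capped weights).  Classification normalizes each locus's POLR2B and
POLR3D scores by the median score of loci dominated by that polymerase
(initial dominance by raw score, iterated to a fixed point, ≤ 10 rounds);
DUAL requires both normalized scores ≥ `dual_fraction` = 0.25 — the
operationalization of "significant amounts of both machineries, comparable
to single-polymerase genes"; UNOCCUPIED requires both raw scores below a
floor of 1 weighted tag.  With < 3 loci per side the classifier falls back
to a raw min/max ratio rule with a warning.  Correlations are Spearman
(average ranks on ties) via the standard library routines; constant columns
are reported missing.  Activator presence = a called peak summit of the
activator within the locus extent ± 400 bp (the promoter window).

## Profiles

**Summit offsets** are strand-corrected (TSS = 0, upstream negative).  For
pol II genes, each factor's median is computed after dropping the
`⌊n/3⌋` lowest-scoring genes (rank rule).  A rank rule cannot be exactly
invariant to cohort composition; the property it guarantees — and that the
suite tests — is that adding a lower-scoring gene never evicts a previously
kept gene.

**3′-end metagenes** reduce tags to estimated fragment midpoints (5′ end
shifted downstream by `fragment_length/2`), removing the systematic
~110-bp fragment-end smear, and average per-gene tracks with equal weight
over a window of −500..+2000 around the RNA 3′ end (minus-strand genes
flipped).  The mean track is smoothed with a 100-bp moving average — an
unsmoothed mean over a ten-gene cohort cannot support a threshold
statistic; raw values are written alongside.  Background is the smoothed
mean over the final 20% of the window, and the **termination extent** is
the far end of the contiguous run, anchored at the 3′ end, that stays above
3× background.  The run-anchored form (rather than the global farthest
exceedance) and the k = 3 threshold were chosen because, at toy cohort
sizes, isolated background blips otherwise set the statistic; both are
flags (`k_background`, `smooth_bp`, `tail_fraction`).  On the benchmark the
pol II extent lands at ≈ 1.15–1.25 kb for a planted 1.2-kb decay and the
pol III extent at ≈ 0.1–0.15 kb for a 50-bp decay.

## Motif annotation

PWMs are built from user-supplied ungapped site alignments with pseudocount
0.5; information content is `2 − H` bits per column.  De novo discovery is
out of scope.  Scanning: log₂ likelihood ratio against a uniform background
on both strands, default floor 60% of the maximum attainable score; windows
containing N are skipped.  Consensus scans use IUPAC degeneracy with a
per-element mismatch allowance — octamer/Z/GA ≤ 2 (the octamer convention),
PSE ≤ 1, TATA exact, because short low-information motifs at 2 mismatches
match essentially everywhere.  The 3′ box is a gapped consensus
(`GTTT N1–4 AANA(A/G)NAGA`), enumerated over all gap lengths in the
+1..+100 3′ flank, best (fewest violations) hit per locus.  TSS-relative
coordinates have no position 0: −1 abuts +1.

Architecture maps mark an activator element occupied iff a peak of the
matching factor lies over the promoter (same chromosome, scanned window
± 100 bp) and the hit is the element hit closest to that peak's summit;
distances are compared in 40-bp bands (the practical resolution of a
summit), with the better motif match breaking ties within a band.  All
other hits are reported crossed-out, as are all hits of factors without a
local peak.

## Synthetic benchmark

The generator emulates the statistical structure of snRNA-type loci:
families of sequence-identical gene bodies (multi-mapping by construction;
each emitted tag's `n_matches` is the exact k-mer occurrence count in the
emitted genome on either strand), identical planted promoter elements in
otherwise unique flanks, uniform Poisson background, point-source promoter
factors, gene-body polymerase occupancy with a linearly decaying downstream
termination zone, and a fragment-end strand model (sense tags upstream,
antisense downstream, offset half a 150-bp fragment, 36-bp tags).

Default benchmark: two chromosomes (200 kb + 100 kb), background 0.005
tags/bp/factor, 16 loci — 10 pol II (one family of three identical copies),
5 pol III (one family of two copies), and one dual-polymerase type 3 locus
carrying both machineries at pol II-typical levels.  Signal sizes per gene
copy: polymerase 300 tags (half in the decay zone for pol II; pol III decay
50 bp, 15% downstream), basal factors 120, SNAPc subunits 100, activators
100.  No quantitative enrichment folds exist for the real loci; these are
calibration choices giving peaks an order of magnitude above the Poisson
threshold, made once.  Planted activator combinations put POU2F1 on 15/16
loci, ZNF143 on 13/16 and GABPA on 7/16, reproducing at desk scale the
reported real-data proportions of roughly 93%, 81% and 45%.  The correlated
two-factor cohort draws per-locus intensities from a bivariate log-normal
whose Gaussian correlation is `2·sin(π·ρ_s/6)` so the latent Spearman
correlation equals the requested ρ_s.

What the benchmark does **not** model: sequencing errors, mappability
holes, diploid variation/SNP-split peaks, duplicate-read structure
(`times_sequenced` defaults to 1), chromatin input bias, or the scale of a
real genome (3 Gb vs 0.3 Mb; thresholds that depend on genome-wide totals
are exercised in a much denser regime here).  Passing tests therefore
demonstrate correctness of the inference chain under its stated model, not
performance on real libraries.

## Sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds reproduce byte-identical
FASTA, tag files and reports.  The test suite and the acceptance script use
desk-scale problems — the 16-locus benchmark, 60-locus correlation cohorts,
and 1-Mb/10⁵-tag background simulations (100 replicates in the test suite,
25 in the script) — chosen so a full run completes in about a minute.
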