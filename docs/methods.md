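# Methods

## The enrichment statistic and its null

For a peak set *P* and a TE class *C* (a set of annotated copies), the
observed statistic is the number of peaks sharing ≥1 bp with the union of
the copies of *C* (half-open interval intersection; a configurable
`min_overlap_bp` counts shared bp against the merged copies, so abutting
fragments are not double-penalised). The null is *matched randomisation*:
each replicate redraws |P| intervals with exactly the observed length
multiset, each placed uniformly among all valid placements. "Valid" means
wholly inside a chromosome, or — when a mappability track is supplied, the
appropriate null for uniquely mapped peak sets — wholly inside one
uniquely mappable block. Random intervals may overlap each other and
copies of other classes; nothing beyond number and length is matched.

With R replicates the enrichment p-value is the add-one estimator
*p = (1 + #{nᵣ ≥ o})/(R + 1)*, which is never 0 and is conservative under
ties; fold is *o/mean(nᵣ)* and is reported as missing (not ∞) when the
class has no copies. q-values are Benjamini–Hochberg across the classes
tested (delegated to statsmodels). Default R = 1000. The unit of counting
is the peak; the copy-unit count (copies overlapped by ≥1 peak) is emitted
alongside, since bar-chart-style figures can be read either way.

Calibration is checked end-to-end: drawing the "observed" peaks from the
null generator itself must produce p ≤ 0.05 in ≈5% of (trial, class) pairs.
Because overlap counts are small integers, the empirical p is slightly
conservative (ties inflate it); with 500 peaks per trial on the default
genome the realised rate is ~0.04.

## Mappability ("uniqueome")

A position *p* is uniquely mappable for read length *k* iff the *k*-mer
starting at *p* occurs exactly once in the union of the genome and its
reverse complement. This is computed exactly by hashing every *k*-mer —
feasible at the ≤10 Mb scale of the synthetic genomes; for a real genome
one would substitute a published uniqueness track in the same
`MappabilityTrack` container (sorted, disjoint per-chromosome intervals;
checked on construction).

## Read assignment policies

"Equal mapping quality" is interpreted as a tied best alignment score;
when scores are absent MAPQ ties are used, and when both are absent every
hit of a multi-hit read is tied. The unique filter keeps a read iff
exactly one hit attains the best score. Inclusive assignment draws one
best hit uniformly at random from a single seeded generator consumed in
read-name-sorted order, so reruns are byte-identical, |inclusive| = |reads|
≥ |unique| always, and singleton reads get identical assignments under
both policies. Binned coverage counts each read once at its midpoint bin
(bin sums conserve read counts).

## Profiles

Anchor profiles average track signal in `bins` equal bins over
±`window` bp around each anchor (peak summit when available, midpoint
otherwise; defaults 4 kb and 100 bp bins — the figure-style window is not
standardised, so these are package defaults). Per-bin means are computed
in genomic orientation and the bin vector is reversed for minus-strand
anchors; this makes the strand-flip involution exact at floating-point
level, not just approximately. Out-of-window anchors are dropped and
counted; zero usable anchors is an error.

Consensus profiles count read midpoints per bin along a consensus element;
with an input library the per-bin ratio is (IP + ε)/(input·s + ε) where
*s* scales input to the IP library size and ε = 0.5 reads/bin avoids
division by zero (configurable). Per-copy signal matrices use
length-normalised means so copies of different lengths are comparable;
copies extending beyond a track's coverage yield missing values, not
zeros. Methylation profiles are coverage-weighted per-bin means with
empty bins missing.

## Modification chemistry and estimation

Read-as-C probabilities per chemistry, for a site with true state
probabilities (p_C, p_5mC, p_5hmC) and an error model with conversion
rate `conversion` and protection failures `fail_*`:

| chemistry | reads C with probability |
|---|---|
| BS | (p_5mC + p_5hmC)(1 − fail_bs) + p_C(1 − conversion) |
| oxBS | p_5mC(1 − fail_oxbs) + (p_C + p_5hmC)(1 − conversion) |
| TAB | p_5hmC(1 − fail_tab) + (p_C + p_5mC)(1 − conversion) |

Default error model: conversion 0.995, fail_bs 0.005, fail_oxbs 0.03,
fail_tab 0.05 — typical magnitudes for well-run libraries (bisulfite
conversion ≥99%, KRuO₄ oxidation and TET protection a few percent short of
complete). `ChemistrySpec.ideal()` gives the error-free model used in
recovery checks. Estimation uses naive proportions, as in standard
practice: total modification from BS, 5mC from oxBS, 5hmC by subtraction
clamped at 0 (the unclamped value is kept in a diagnostic field), or 5hmC
directly from TAB. Wilson 95% CIs per proportion; the subtraction CI uses
the normal approximation with summed binomial variances. An important
consequence of the subtraction: sd(5hmC‑hat) = √(σ²_BS + σ²_oxBS), e.g.
0.020 at depth 1000 for truth (0.6, 0.2) — roughly √2–1.6× the error of a
single proportion at the same depth.

The amplicon workflow filters CpGs at ≥100 reads *jointly* across the
chemistries being combined (a subtraction needs both counts; a
per-chemistry mode exists), then averages biological replicates per CpG
unweighted, reporting the replicate count. Genome-scale data merge CpG
dyad strand calls by summing counts onto the plus-strand coordinate;
amplicon mode keeps the sequenced strand. Region aggregation is
coverage-weighted by default. Group comparisons: two-sided rank-sum, with
full enumeration of rank assignments for n₁+n₂ ≤ 12 (twice the smaller
tail, capped at 1 — valid under ties, where the permutation distribution
of U is asymmetric) and the tie-corrected normal approximation otherwise;
or Welch's t.

## Expression pooling and gene linking

Reads are pooled per repeat class; a read overlapping copies of k > 1
classes contributes 1/k to each (a drop-to-unassigned mode exists), and
reads overlapping no copy are tallied as unassigned, so pooling conserves
reads. Size factors are plain median-of-ratios: the per-sample median of
count/geometric-mean ratios over features positive in all samples. (Note
this is equivariant in factor *ratios*: scaling one sample by c also moves
every geometric mean by c^(1/m).) TE copies link to a gene when they
overlap the distal end of an interaction pair whose promoter belongs to
that gene; a gene linked to both bound (NOS+) and unbound (NOS−) TEs
counts as NOS+ by default (an exclusive mode drops it from both).

## The synthetic-data generator

Defaults are sized for a laptop/CI run: a 2 Mb single-chromosome genome
with five families — three 6.5 kb L1-like families at 1.5/3/10%
divergence with 50–70% 5′-truncation probability (geometric offsets, mean
2 kb, so a full-length/truncated dichotomy exists around the 5 kb
threshold), a 600 bp LTR family and a 150 bp SINE. Copies are placed
uniformly at random without overlap (longest-first over the remaining free
space, which keeps placement exactly uniform among valid positions),
mutated per-base at the family divergence rate, and reverse-complemented
on minus-strand insertions. Requesting >80% TE content is an error.

ChIP simulation binds full-length copies of configured families with a
per-family probability, placing one peak per bound copy inside its 5′
window (900 bp, strand-aware) plus uniform background peaks; a planted
peak enters the *unique* peak set only when its copy is diverged beyond
4% — at ~1 substitution per 25 bp a 50 bp read almost surely spans a
diagnostic difference, so divergence is what rescues mappability, exactly
the young-vs-old asymmetry the analyses are about. Reads are drawn per
peak (Poisson depth) over a uniform background, and each read's hit set
lists every exact occurrence of its sequence in the genome (an optional
edit-distance mode admits approximate matches), so tied multi-hit reads
arise naturally at young copies. For exact fold planting,
`simulate_peaks_with_fold` uses the closed-form null overlap probability
p₀ to mix target-overlapping and target-avoiding placements so the
expected enrichment fold is exact.

Bisulfite simulation draws per-site depth Poisson(mean) per chemistry and
unconverted counts binomially at the chemistry matrix probability;
interaction/count simulation links a configurable fraction of NOS+/NOS−
copies to distinct gene promoters and draws negative-binomial counts
(dispersion 0.1, lognormal gene-to-gene spread) with a configurable fold
on NOS+-linked genes. Every simulator is a pure function of
(config, seed) and emits a truth table sufficient to score recovery.

What the generator does *not* emulate: sequencing errors and base
qualities, indels, fragment-length effects, chromatin-driven coverage
biases, PCR duplicates, incomplete annotations, and reverse-strand read
sampling (reads are drawn from the forward strand; hit-set ambiguity is
still exercised because duplicated sequence is duplicated on both
strands). Passing recovery tests therefore demonstrates correctness of
the analysis arithmetic under the stated statistical model, not
robustness to all real-data artefacts.

## Numerical and design choices

- Coordinates are 0-based half-open internally; RepeatMasker/Bismark
  1-based inputs are converted at the I/O boundary (strand `C` → `-`).
- "Full length" is strictly > 5000 bp (the ">5 kb" convention);
  configurable.
- Overlap requires ≥1 shared bp by default; no summit-containment rule.
- Family age order is supplied explicitly per superfamily; absent that,
  families rank by mean divergence (younger = lower).
- Ties in per-copy matrix sorting are broken stably by input order;
  missing values sort last.
- Empirical p-values use many randomisations (R = 1000) rather than a
  single random control, and report the null spread.
- Problem sizes in tests and the acceptance script (2 Mb genome, 500–2000
  peaks, depth ≤1000, ≤500-interval oracle instances) were chosen to give
  each check clear statistical resolution while keeping a full run in the
  minutes range on one CPU.

## Known limitations

- The exact-k-mer uniqueome and exact-occurrence hit sets are desk-scale
  stand-ins for aligner behaviour; they have no mismatch tolerance by
  default.
- The subtraction estimator's per-site 5hmC error is irreducibly ~√2
  larger than a single-proportion estimate at equal depth (see above);
  deep coverage or site averaging is needed for tight per-site claims.
- Conversion-error correction (inverting the chemistry matrix) is
  available in spirit through the simulator's matrix but the estimator
  deliberately uses naive proportions, matching common practice.
- DESeq2-style dispersion modelling and Wald testing are out of scope;
  normalised-count group comparisons stand in for them.
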