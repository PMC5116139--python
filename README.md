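# retroepi

Transposable-element-centric epigenomic analysis: do regulatory factors
(e.g. the TET dioxygenases) bind particular repeat classes, and what do DNA
modification states look like at the copies they bind?

Repeats are the hard case for ChIP-seq and bisulfite analysis because young
TE copies — the biologically active ones — are nearly identical in sequence
and therefore nearly unmappable with unique reads. `retroepi` implements the
analysis toolkit for this setting:

- **Peak–TE-class enrichment against a matched random null.** For each TE
  class, count peaks overlapping ≥1 annotated copy and compare with random
  interval sets of *equal number and lengths*, placed uniformly anywhere in
  the genome (for inclusively mapped peaks) or wholly inside uniquely
  mappable regions (for uniquely mapped peaks). With observed count *o* and
  null counts *n₁…n_R*, the enrichment p-value is the add-one empirical
  estimator *p = (1 + #{nᵣ ≥ o}) / (R + 1)*, fold = *o / mean(nᵣ)*,
  corrected across classes by Benjamini–Hochberg.
- **Two multi-mapping read policies.** *Unique*: keep a read only when
  exactly one hit attains its best alignment score. *Inclusive*: assign each
  tied-best read to one of its best hits uniformly at random (seeded).
  Peaks from inclusive mapping are "ambiguous" — not attributable to a
  specific copy, but bounding how many copies may be bound.
- **Family-age overlap summaries.** Per TE family, ordered young→old, the
  fraction of full-length (>5 kb) copies overlapped by unique and by
  ambiguous peaks.
- **Meta-profiles.** Strand-aware signal around peak anchors, per-copy
  signal matrices, and coverage along a consensus element (the classic
  LINE-1 5′-UTR profile), IP/input with a pseudocount.
- **BS/oxBS/TAB arithmetic.** BS reads C for 5mC+5hmC, oxBS for 5mC only,
  TAB for 5hmC only; so 5hmC = BS − oxBS (clamped at 0) or directly from
  TAB. Amplicon mode applies a joint ≥100-read coverage filter and averages
  biological replicates per CpG; group comparisons use exact/asymptotic
  Wilcoxon rank-sum or Welch's t.
- **Repeat-class expression pooling** with median-of-ratios size factors,
  and linking of TE copies to genes through promoter-capture interaction
  pairs.
- **A synthetic-data generator** that produces every input — genome with TE
  families of configurable age and 5′ truncation, peaks, multi-hit reads,
  cytosine reports under an explicit conversion-chemistry error model,
  interaction and count tables — with planted ground truth, so the whole
  pipeline is testable offline.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
2 Mb synthetic genome (five TE families; peaks planted on full-length young
L1 copies and on an enhancer-like LTR family) and write tables to
`results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_te_class_enrichment.py
```

```
--- inclusive mapping (182 peaks) ---
class  observed  expected_mean  expected_sd     fold        p        q  observed_copies
 SINE         2          7.964     2.703333 0.251130 0.998002 0.998002                2
 LINE        93         88.847     6.488736 1.046743 0.289710 0.434565               73
  LTR        48          8.242     2.755182 5.823829 0.000999 0.002997               47
--- full-length L1 copies overlapped by peaks (young -> old) ---
 family  age_rank  n_copies  frac_unique_peaks  frac_ambiguous_peaks
 L1Md_T         0        50           0.320000              0.860000
 L1Md_A         1        44           0.204545              0.204545
L1Md_F2         2        32           0.375000              0.375000
```

Reading this: the LTR class, where peaks were planted on half the copies,
comes out ~5.8-fold enriched over the matched null (q = 0.003); LINE does
not reach significance as a class because the planted young-L1 peaks are
diluted by the large unbound LINE fraction of the genome. The family-age
table shows the signature pattern at young L1s: 86% of full-length young
copies are covered by ambiguous (inclusive-mapping) peaks, against a
background-level fraction at the older families, while unique mapping sees
far fewer. `analysis/03_profiles.py` through `05_expression_links.py`
continue with consensus 5′-UTR profiles, bound-vs-unbound methylation
comparisons and the enhancer-TE/gene expression analysis.

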