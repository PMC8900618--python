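# stemqc

Genome characterization for cultured human pluripotent stem cell lines.

Stem cell lines accumulate genetic variation in culture — whole-arm
gains, mosaic copy-number changes, copy-neutral loss of heterozygosity,
and point mutations in cancer- and disease-associated genes — on top of
the inherited variation (ancestry, relatedness, polygenic background)
of the embryos they came from. `stemqc` implements the computational
side of a WGS-based characterization pipeline for such lines, for
groups who need to pick lines rationally or monitor cultures:

* **Large CNV scanning** from 100-kbp binned normalized read depth,
  scoring each sample against the cohort with
  `Z(S, I) = |coverage(S, I) − median(I)| / MAD(I)`, reporting events
  spanning ≥ 10 bins with Z > 5 and sharp boundaries, and classifying
  each as **fixed** or **mosaic** (divergence of mean CN from the
  nearest integer, P < 1e-3) with a cellular-fraction estimate from the
  mixture model E[CN] = 2 + f·(c − 2).
* **Allelic-imbalance segmentation** of phased heterozygous allele
  depths (binomial likelihood-ratio scan, LOD > 20 over > 1 Mbp), with
  dup/del/CN-LOH classification against coverage and the CN-LOH
  acceptance rule (mosaic and telomere-extending — a single mitotic
  crossover in culture, not an inherited run of homozygosity).
* **Relatedness and ancestry**: VIF LD pruning (50/5/2), PLINK-style
  method-of-moments IBD (π̂ = IBD1/2 + IBD2, kinship = π̂/2, direct
  relatives at π̂ ∈ [0.35, 0.70]), and ancestry fractions from a
  PCA + linear model trained on a labeled reference panel.
* **Polygenic scores**: Σ dosage × weight over p < 0.5 markers,
  residualized on 12 PCs, z-scored so controls have mean 0 / SD 1,
  outlier traits at |z| ≥ 2, and an "all-purpose control" ranking by
  Σ|z| across traits.
* **SNV prioritization cascade**: HC-HQ genotype filters → consequence
  bins → deleterious (AF < 1e-3, CADD > 20, DANN > 0.99) → cancer
  (COSMIC Tier 1, ≥2 observations, FATHMM-cancer), fertility
  (fertility gene, LOEUF ≤ 0.33, CGD autosomal dominant) and disease
  (LOEUF < 0.33, CGD AD, FATHMM-XF > 0.75, DANN > 0.999, AF < 1e-5)
  shortlists.
* **Array-intensity (IRS) validation** of CNV calls with an exact
  pooled rank-sum test, cohort FDR = 2 × fraction(p ≥ 0.5), and
  per-type length-threshold search.
* **Recurrence analyses**: minimal shared duplicated region by boundary
  sweep, satellite-repeat (GGAAT)n breakpoint motif scanning, GC
  profiles, and OLS burden-vs-covariate regression.
* **Per-line reporting** with a transparent tiered selection scheme
  (pass / caution / avoid, with reasons).

A seeded synthetic-data module (`stemqc.sim`) generates every input
with known ground truth — implanted fixed/mosaic events, imbalance
segments, gene-dropped pedigrees, annotated variant tables with
independently computed cascade truth, and carrier-shifted array
intensities — so the whole pipeline is exercisable and testable without
access to controlled human data.

## Worked example

Run the demo pipeline — 12 simulated lines carrying a fixed trisomy-like
gain, a 50%-mosaic gain, a 60%-mosaic loss and a telomeric mosaic
CN-LOH, plus a sibling pair:

```bash
stemqc pipeline --seed 0 --out-dir demo_run
```

The manifest it prints ends with:

```
"n_truth_events": 4,
"n_large_calls": 3,
"n_accepted_cnloh": 1,
```

i.e. the three depth-visible events are recovered by the coverage scan
(CN-LOH is invisible in depth and is instead the one accepted BAF
event). `demo_run/large_cnv_calls.tsv` shows the calls with their Z
scores, mosaicism p-values and cell fractions:

```
sample  start     end       kind  mean_cn  status  cell_fraction
S001    10000000  16000000  dup   2.993    fixed
S002    30000000  35000000  dup   2.497    mosaic  0.497
S003    50000000  56000000  del   1.402    mosaic  0.598
```

S001's fixed gain sits at CN ≈ 3 (p_mosaic ≥ 1e-3 → fixed, no fraction
reported); S002's mosaic gain at CN ≈ 2.5 implies roughly half the
cells carry one extra copy (f̂ ≈ 0.50); S003's CN ≈ 1.4 implies a
single-copy loss in ≈ 60% of cells. `demo_run/selection.tsv` then
applies the tiered policy, e.g.:

```
line  overall  reasons
S001  avoid    large_fixed_sv: 1 (tier avoid); ...
S002  caution  large_mosaic_sv: 1 (tier caution); ...
```

— a fixed large structural variant rules a line out, while a mosaic one
only warrants caution because such lines can often be rescued by
sub-cloning or an earlier passage.

Equivalent library calls: `stemqc.sim.gen_coverage`,
`stemqc.doc_cnv.scan_large_cnvs`, `stemqc.baf.segment_imbalance`,
`stemqc.kinship.pairwise_relatedness`, `stemqc.snv.run_cascade`,
`stemqc.irs.irs_table`, `stemqc.report.build_report` /
`select_lines`.

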