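# Methods

`stemqc` characterizes the genomes of cultured pluripotent stem cell
lines from whole-genome-sequencing-derived inputs: binned normalized
read depth, phased allele depths at heterozygous sites, cohort genotype
matrices, annotated variant tables, polygenic-score weights and array
probe intensities. This note describes the statistical models, the
defaults and why they are set where they are, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Large CNVs from depth of coverage

Coverage is analyzed on non-overlapping 100-kbp bins on a normalized
copy-number scale (diploid = 2). For sample S over a bin interval I the
score is

    Z(S, I) = |coverage(S, I) − median(I)| / MAD(I)

with the median and MAD (raw, no 1.4826 consistency factor) taken
across samples over the same interval. A mosaic event present in a
fraction f of cells at integer copy number c has expected normalized
coverage 2 + f·(c − 2), so a fixed trisomic arm sits at 3 and a
half-fraction gain at 2.5.

**Search.** Candidate intervals are seeded at single bins with Z > 3
and grown by bin membership using the halfway-return rule: a
neighboring bin joins the interval while its coverage has *not* moved
more than halfway from the inside coverage back toward that bin's
cohort median, and terminal bins that have returned are trimmed.
Reported calls must span at least 10 bins (1 Mbp), score Z > 5, deviate
from the cohort median by at least `min_dev` (default 0.1 copies), have
sharp boundaries (the first bin outside each end has returned more than
halfway) and inside-consistent terminal bins; overlapping candidates
resolve to the highest Z (ties: longer, then leftmost) and surviving
calls separated by at most one bin merge.

Two of these rules deserve comment, because the interval Z statistic
alone cannot anchor them:

* Z is self-normalized — numerator and denominator both shrink like
  1/√(bins) — so under event-free noise Z does not decay as intervals
  grow, and any pure hill-climb on Z either stalls on MAD jitter or
  ratchets far past true boundaries. Growing intervals by the
  halfway-return membership rule instead pins boundaries per-bin: at
  depth 30 the per-bin noise SD is ≈0.014 copies, so deciding whether a
  bin sits at the event level or the background level is a >7σ decision
  for any event with f ≥ 0.2. In simulation this recovers implanted
  50-bin events with zero or one bin of boundary error.
* The `min_dev` effect-size floor exists because Z, being a ratio, is
  scale-free: with a finite cohort the across-sample MAD is noisy and
  event-free data can drift above Z = 5. An absolute minimum deviation
  of 0.1 copies (7× the 10-bin-scale noise SD at depth 30, and half the
  smallest cell fraction the recovery contract targets) is the
  deterministic stand-in for the manual review a human analyst would
  apply, and keeps null cohorts of 25,000 bins × 20 samples free of
  calls.

On matrices small enough to enumerate, the search provably reduces to
"apply the acceptance rules to every interval": the test suite checks
exact agreement with an exhaustive all-intervals oracle.

**Mosaicism.** Each reported call is tested for divergence of its mean
copy number ĉ from the nearest non-diploid integer consistent with its
type (3+ for gains, 1/0 for losses): a two-sided t test using the
between-bin standard error within the call. P < 1e-3 declares the call
mosaic — the threshold at which, by construction and by measurement,
fewer than 1% of event-free samples are flagged — and the cellular
fraction is estimated as f̂ = |ĉ − 2| under the single-copy-step
mixture, clipped to (0, 1]. Multi-copy amplicons therefore report f
clipped at 1. Zero within-call variance is degenerate and reported
fixed.

**Small CNVs.** Externally genotyped calls are filtered by the length
thresholds established via array validation (deletions ≥ 1,117 bp,
duplications ≥ 2,750 bp), capped at 1 Mbp (longer events belong to the
scan above), and masked against large calls in the same sample.
Cross-sample identity is ≥50% reciprocal overlap with transitive
closure; this definition underlies both the recurrence screen (present
in ≥5 stem-cell lines, absent from European controls, <10% of other
controls) and singleton counting (equivalence class of size one, after
collapsing each sibship to a single representative).

## Allelic imbalance and CN-LOH from phased BAF

At phased heterozygous sites the B-allele frequency hap1/(hap1+hap2)
has expectation 0.5; an event at cell fraction f shifts it to

    CN-LOH:          (1 + f) / 2
    single-copy dup: (1 + f) / (2 + f)
    single-copy del: 1 / (2 − f)

on the over-represented haplotype. Segmentation scores each site with a
base-10 binomial log likelihood ratio at a fixed alternative deviation
(0.1), extracts maximal positive-scoring runs per orientation, then
refines each run once at its estimated deviation so that near-balanced
boundary sites — which score strongly negative under the re-estimated
alternative — drop out. Segments with LOD > 20 spanning > 1 Mbp are
reported. The refinement step matters for the CN-LOH acceptance rule: a
fixed run of homozygosity must estimate f̂ = 1 exactly (every site
fully unbalanced), not 0.99, because acceptance requires the event to
be *mosaic* (f̂ < 1) *and* telomere-extending (within one bin of a
chromosome terminus) — the signature of a single mitotic crossover
acquired in culture rather than inherited homozygosity.

Classification against coverage: mean CN over the segment significantly
above 2 (t test, α = 1e-3) is a duplication, significantly below a
deletion, otherwise copy-neutral; the fraction inverts the matching
mixture identity (f = 4d/(1−2d) for gains, 4d/(1+2d) for losses, 2d for
CN-LOH, where d is the BAF deviation). Inverted fractions outside
(0, 1] mark the segment ambiguous; fractions under 0.1 are flagged
low-fraction. Phase-switch errors are not modeled — the simulator emits
perfect phase — so real-data deviations estimated across long segments
would be attenuated by switch errors in ways these tests do not probe.

## Relatedness and ancestry

Sites with minor allele frequency below 1% are removed, then LD-pruned
with the variance-inflation-factor criterion (windows of 50 sites, step
5, VIF ≤ 2, computed as the diagonal of the inverse correlation matrix;
a small ridge keeps perfectly duplicated sites invertible so their
astronomical VIF removes them). Pairwise IBD0/1/2 comes from the
method of moments on identity-by-state counts with expected IBS
proportions from allele frequencies, solved sequentially and clipped to
the simplex; π̂ = IBD1/2 + IBD2 and kinship = π̂/2. Pairs with π̂ in
[0.35, 0.70] are directly related; IBD2 ≥ 0.10 separates full siblings
(expectation 0.25) from parent-child (expectation 0). π̂ < 0.10 is
unrelated; everything else (half siblings, duplicates) is "other".

Ancestry fractions are linear predictions from the first three
principal components of the standardized-genotype relationship matrix,
trained on labeled reference samples (pure or admixed labels), clipped
to [0, 1] and renormalized. PCs are defined up to sign; tests compare
absolute correlations.

## Polygenic scores

Raw score = Σ dosage × weight over markers with source-study p < 0.5;
missing dosages are mean-imputed at the marker. Raw scores are
residualized on the first 12 PCs by OLS fit on the control cohort, and
residuals are z-scored by the control mean and SD (n−1), making control
moments exactly 0/1. |z| ≥ 2 flags an outlier trait. The all-purpose
ranking sorts lines ascending by Σ_traits |z| (ties by line id), so
rank 1 is the line closest to the population mean across every scored
trait. Twelve PCs is the default because components beyond that showed
no correlation with raw scores in the data the procedure derives from;
it is exposed as a parameter.

## SNV prioritization cascade

Stages in order, with missing annotations failing their stage
(conservative shortlists):

1. **HC-HQ**: FILTER = PASS; some genotype with DP ≥ 10, GQ ≥ 20 and
   allele fraction ≥ 0.2 (read from allele depths); outside
   low-complexity/segmental-duplication regions; population-database
   filter PASS or missing.
2. **Consequence bins** (canonical transcript): LoF = {frameshift,
   splice acceptor, splice donor, stop gained}; missense additionally
   includes in-frame indels, start/stop loss, protein-altering;
   synonymous; other.
3. **Deleterious**: LoF/missense, reference AF < 1e-3, CADD phred > 20
   (top 1% of the phred deleteriousness scale, since the scale maps s
   to the top 10^(−s/10) fraction), DANN > 0.99.
4. **Cancer**: COSMIC Tier-1 gene, variant observed ≥ 2 times in
   COSMIC, FATHMM-cancer positive.
5. **Fertility**: literature fertility gene, LOEUF ≤ 0.33 (inclusive),
   CGD autosomal dominant.
6. **Disease** (autosomes only): LOEUF < 0.33 (strict), CGD autosomal
   dominant, FATHMM-XF > 0.75, DANN > 0.999, AF < 1e-5.

The two LOEUF edge semantics are deliberate: the source thresholds are
phrased once as "0.33 or less" and once as "below 0.33", and each
filter honors its own phrasing (both are configurable). The cascade is
monotone (each stage's survivors are a subset of the previous) and
idempotent, and the simulator labels every generated record with
independently computed truth flags; tests require exact agreement.

## Array-intensity (IRS) validation

For a CNV call with predicted carriers, probe intensities inside the
call are ranked across samples per probe; the pooled carrier rank sum
is tested one-sided (low tail for deletions, high for duplications)
against the exchangeable null — exactly, by convolving the
without-replacement per-probe rank-sum distribution, when the state
space is small, otherwise by normal approximation. Ties get midranks;
all-tied probes give p = 0.5. The cohort FDR estimate is
2 × fraction(p ≥ 0.5): null p-values are uniform so the mass at or
above 0.5 counts half the false calls, while true calls concentrate
near 0. Length-threshold search returns the smallest observed length
cutoff whose retained calls meet the target FDR (default 3%), per CNV
type, flagging unattainable targets.

## Recurrence analyses

The minimal shared region of a set of duplication intervals is the
maximum-overlap-depth segment found by a boundary sweep (union of tied
segments when depths tie), verified against per-base counting.
Breakpoint windows (±500 bp) are scanned for tandem runs (≥3 units) of
a satellite repeat unit, default GGAAT, matching all cyclic rotations
and reverse-complement rotations — the window and unit-count defaults
are package choices, as the motif observation they operationalize was
presented without numeric criteria. GC content per interval comes from
an indexed FASTA with N-only intervals excluded. Burden regression is
plain OLS of per-line variant counts on covariates with dummy-coded
categoricals, rank-deficient columns dropped, and two-sided t
p-values; count models (Poisson/negative binomial) would be the
natural extension but are not the default since the procedure this
mirrors used linear regression.

## Reporting and selection

`build_report` aggregates counts per line; modules that were not run
leave NA fields (never silent zeros), and calls spanning ≥200 bins
count as aneuploidy. The default selection policy maps findings to
tiers: aneuploidy, large fixed SVs, cancer- and disease-shortlist SNVs
→ avoid; large mosaic SVs (rescuable by sub-cloning or an earlier
passage), accepted CN-LOH, fertility SNVs, and more than 3 outlier PRS
traits → caution. The overall verdict is the worst tier, every non-pass
carries a reason, and non-computable criteria (licensing,
freedom-to-use) are accepted only as user-supplied booleans. The
PRS-outlier count cutoff (3) is a package default; the source scheme
flags outliers without prescribing a count.

## The simulator

`stemqc.sim` generates every input with known truth from one seeded
configuration; identical configurations give byte-identical outputs.

* **Coverage**: Poisson read counts per bin (expected
  `mean_depth × bin_size / read_length` ≈ 20,000 at depth 30), scaled
  by true CN/2; negative binomial (var = μ + φμ²) available for
  over-dispersion. Normalization divides by the per-sample *median* bin
  count — median rather than mean because implanted events inflate the
  mean and would bias recovered copy numbers (a 50-bin CN-3 event on a
  1,000-bin genome would read ≈2.93 and misclassify as mosaic) — then
  by the per-bin across-sample median, times 2.
* **Phased counts**: het sites uniform over the genome; depth Poisson
  scaled by local CN; hap1 binomial at the mixture BAF above. Perfect
  phase, no switch errors.
* **Pedigrees**: founder frequencies uniform on [maf_floor, 0.5];
  gene-drop with independent sites (every site an independent meiosis),
  so sibling IBD fractions converge to 1/4, 1/2, 1/4 per site; labeled
  founder alleles give realized IBD truth per pair. An optional
  block-copy LD mode tiles perfectly correlated site blocks to exercise
  pruning. A Balding-Nichols generator provides divergent populations
  (configurable F_ST) and admixed samples for ancestry tests.
* **Variant tables**: annotations drawn so a realistic trickle survives
  each stage; truth flags computed by an independent plain re-statement
  of the thresholds sharing no code with the cascade module.
* **Array intensities**: standard-normal probe intensities; carriers of
  TRUE calls shift by a configured effect (default 3 SD, sign by type);
  FALSE calls leave carriers exchangeable with non-carriers.

What the simulator does *not* emulate — GC waves, mappability and
tagmentation bias, alignment artifacts, LD beyond block copies,
phase-switch errors, genotyping error — bounds what passing tests say
about real data: they validate the statistical machinery under its own
stated noise model, not robustness to platform artifacts. The null
calibration of the mosaicism test, in particular, is a statement under
Poisson bin noise; an over-dispersed platform would need the negative
binomial setting and recalibration.

## Problem sizes and numerical notes

Tests and the acceptance script run at desk scale, chosen to keep the
whole suite in a couple of minutes while leaving wide statistical
margins: null calibration uses 20 cohorts of 243 samples × 25,000 bins;
CNV recovery 50 seeds × (20 samples × 800 bins) per cell fraction;
exhaustive-oracle matrices are 10 × 200; kinship uses 20 sibling pairs
× 10,000 sites; ancestry panels 200 reference samples × 20,000 sites at
F_ST 0.15; IRS mixtures 50 seeds × 500 calls. Degenerate inputs are
handled explicitly: zero MAD flags interval statistics degenerate (Z
becomes +inf, never NaN); zero within-call variance forces the
mosaicism test to p ∈ {0, 1}; all-tied intensities give p = 0.5;
constant genotype sites are removed before VIF; collinear PCs and
covariates are dropped with a note. Wherever ties can occur in sorting
(candidate dominance, ranking) the tie-break is deterministic and
documented in the function.
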