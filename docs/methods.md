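# Methods

This note documents the generative model behind the synthetic cohorts, the
estimators and tests implemented, the numerical choices, and what the test
suite's passing does and does not establish about real data.

## Cohort and covariate model

A cohort is three diagnosis groups — schizophrenia (SCZ), bipolar disorder
(BPD), unaffected controls (CTRL) — with default sizes 35/32/35. Covariates
are independent Gaussians chosen to resemble brain-bank demographics: brain
pH N(6.5, 0.25), postmortem interval N(30 h, 13 h) truncated at 1 h, age
N(45 y, 9 y), brain weight N(1450 g, 130 g); sex is Bernoulli with male
fraction 0.65; age of onset (cases only) is age minus U(10, 30) years. None
of these distributions matter to the estimators; they exist so confounder
screening has realistic material to work on.

## Genotypes

The 83 anonymous region SNPs draw a minor-allele frequency from U(0.05, 0.5)
and genotypes as two independent Bernoulli(MAF) alleles — i.e. exact
Hardy–Weinberg equilibrium, no linkage disequilibrium. LD is deliberately
omitted: every implemented statistic treats SNPs marginally, so correlation
between SNPs would change nothing but the effective family size of the scan.
rs2229864 defaults to MAF 1/3, giving expected heterozygosity 2p(1−p) = 4/9
≈ 44.4 %. rs7341475 defaults to G-allele frequency 0.80; no published
frequency was adopted, and the value is an explicit configuration knob.
GGC repeat alleles come from a frequency map with 94.8 % of mass on 8 and 10
repeats and the remainder on rare 12–16-repeat alleles.

## Latent expression model

Per subject the generator draws:

- total expression on the log2 scale, N(0, 0.5) — no group effect, matching
  a null total-expression difference;
- polyA (short-isoform) proportion = group mean (SCZ 0.087, BPD 0.060,
  CTRL 0.085) + 0.00035·(PMI − mean PMI) + N(0, 0.02);
- microexon skipping = sex×rs7341475 cell mean (male-GG 0.158, male-A 0.226,
  female-GG 0.1643, female-A 0.1464) − 0.08·(pH − mean pH) + N(0, 0.05);
- a signed allelic deviation for rs2229864 heterozygotes whose magnitude is
  half-normal with scale 0.0323, shifted by +0.0672 in schizophrenia.

Proportions are generated on the linear scale and clipped to
(1e-4, 1 − 1e-4); a logit-scale noise option exists for users who prefer a
boundary-respecting model. The per-subject SDs (0.02 for polyA, 0.05 for
skipping) are design choices — no per-sample variance is published for such
assays at this scale — sized so that single-cohort group contrasts at the
configured effect sizes are comfortably but not trivially detectable,
and exposed in `ExpressionModel`.

The covariate slopes are sized to make pH the dominant confounder of
skipping (partial F ≈ 12 at n ≈ 100) and PMI a borderline confounder of the
polyA proportion (partial F ≈ 5), i.e. one clearly-selected and one
sometimes-selected confounder for the screening logic to exercise.

The two AEI scale parameters are set by half-normal threshold arithmetic,
not by fitting: with base scale σ, the probability that a non-SCZ
heterozygote's allelic ratio exceeds 1.2 (deviation 0.04545) is 16 % when
σ = 0.0455/1.405 ≈ 0.0323, and with shift s the SCZ probability is 75 % when
(s − 0.04545)/σ = Φ⁻¹(0.75), giving s ≈ 0.0672. The measurement layer adds
≈ 0.005 SD to the recovered deviation, which moves these fractions by less
than one percentage point.

## Measurement rendering

- **qPCR**: Ct = 25 − log2(relative quantity) + N(0, 0.15) per replicate,
  three replicates; the reference-gene baseline of 25 cycles is arbitrary
  and cancels in every ΔCt. The polyA assay's quantity is total × polyA
  fraction, so 2^(Ct_total − Ct_polyA) inverts exactly to the latent
  fraction in the noiseless limit. The 6-point standard curve per assay uses
  Ct = 25 − log10(dilution)/log10(1+E) with E = 0.99 (RELN), 0.95 (CHL1,
  polyA).
- **Peaks**: retained and skipped heights are the latent fractions times a
  lognormal total signal, each peak carrying independent lognormal noise of
  CV 3 % (the level used in the oligo mixing series), three replicates.
- **Allele signals**: per replicate a log10 intensity N(3.0, 0.3); measured
  T fraction = true fraction + 0.02·(log10 I − 3.0) + N(0, 0.01), split over
  the two channels. Three gDNA and six cDNA replicates per subject. The
  0.02-per-decade bias is small enough to keep fractions inside (0, 1) but
  large enough that an uncalibrated analysis is visibly shifted.
- **Fragments**: rendered exactly (no sizing jitter), so round-trip
  concordance of the callers is a property of the calling logic; the callers
  themselves tolerate ±2 bp (RFLP) and ±1 bp residue (repeats), which covers
  typical gel/capillary jitter.

## Estimators and tests

**ΔCt.** `relative_expression(target, reference)` reports
Δ = Ct_target − Ct_reference and linear value (1+E)^(−Δ). The default is
E = 1 (perfect doubling); using measured efficiencies is a switch
(`use_measured_efficiency`) because published ΔCt analyses typically report
efficiencies without folding them into the arithmetic, and the default keeps
the two conventions cleanly separated. Replicate SD > 0.5 cycles flags a
record (conventional qPCR QC) without discarding it.

**Microexon.** Peak-height (not area) ratios; replicates are averaged on the
proportion scale and then log10-transformed ("transform the proportion", so
aggregation precedes transformation); zeros are floored at 1e-4 before the
log. The skipping proportion (not retention) is the analysed quantity.

**AEI.** The calibration regresses gDNA-heterozygote T fractions on log10
total intensity — the same axis the bias acts on; a linear-intensity option
exists. All available gDNA heterozygotes feed the calibration (not only the
cDNA-informative subset): the calibration estimates an assay property, and
more points means a tighter line. Expected p for a sample is evaluated at
its mean replicate intensity. The display ratio uses the corrected fraction
p* = observed − (expected − 0.5), so ratio = 1 ⇔ AEI = 0, and the 1.2/1.4
class thresholds are strict.

**ANOVA.** All model F tests use type-I (sequential) sums of squares with
confounders entered before the term of interest, computed by nested least
squares with explicit column blocks (formula interfaces can silently reorder
terms, which changes sequential SS). With no confounders this reduces
exactly to the classical one-way ANOVA, which the tests verify against an
independent implementation. Only the single most significant screened
confounder is carried into adjusted models; multi-confounder adjustment is a
caller choice. Pairwise group contrasts refit the confounder on the
two-group subset.

**HWE.** The exact conditional test: condition on allele counts, enumerate
all heterozygote counts of matching parity, sum the probabilities of
configurations no more probable than the observed one (log-gamma arithmetic,
normalized in place). Verified exhaustively against an exact-fraction
enumeration oracle for all tables with total ≤ 20.

**SNP QC.** pass ⇔ HWE P ≥ 0.05/n_SNPs and MAF strictly above 5 %. For
passing SNPs a homozygote class with ≤ 5 subjects is pooled into the
heterozygotes before modelling, and the pooling is recorded.

**Scan and permutation.** The scan fits phenotype ~ confounder + genotype
factor per SNP via per-SNP QR factorizations reused across permutations
(83 SNPs × thousands of permutations would be prohibitive through a formula
API; the fast path is cross-checked against statsmodels on single fits).
The family-wise correction permutes the phenotype across subjects, keeps
genotypes and confounders fixed, records each permutation's minimum nominal
P over the family, and stops when 20 permutation minima are ≤ the observed
minimum (ties count as hits); corrected P = 20/N. "Instances" are counted
per permutation (family-wise min-P), not per SNP×permutation; the latter
reading would estimate a different, non-family-wise quantity. If the
permutation cap (default 100,000) is reached first, the (hits+1)/(N+1)
upper-bound estimator is reported and flagged. The 20/N stopping estimator
is slightly conservative (upward-biased by roughly 1/20), which the type-I
calibration test reflects.

**AEI × SNP.** Heterozygotes vs pooled homozygotes per SNP, one-way ANOVA
(df = 1), same permutation machinery; SNPs with fewer than two subjects in
either class are skipped with the reason recorded.

## Problem sizes in the shipped checks

The calibration checks run at sizes where binomial/Gaussian standard errors
make the assertions meaningful: 25 default cohorts for group-mean recovery,
2,000 alleles for the repeat-frequency check, 10,000 subjects for
heterozygosity, ~1,000 informative samples for the AEI classification rate,
200 null cohorts (permutation cap 20,000) for the family-wise type-I error,
and 10 dilution series for the validation slope.

## What the synthetic cohorts do and do not establish

The generator reproduces the statistical *structure* the analysis assumes —
group means, covariate slopes, HWE genotypes, intensity-dependent allelic
bias, replicate noise — so passing tests establish that the estimators are
unbiased and calibrated under that structure, and that the inferential
machinery controls its error rates. It does not emulate: linkage
disequilibrium, population stratification or relatedness; RNA-quality
gradients correlated with diagnosis; amplification-curve or electropherogram
artefacts (Ct values and peak heights are the atomic inputs); allele-specific
probe cross-hybridization beyond a linear intensity bias; or missingness.
Agreement on synthetic cohorts therefore validates the pipeline's
arithmetic and calibration, not any biological claim about real donors.

## Known limitations

- The permutation corrector returns an estimator, not an exact P; below
  target_hits/cap it degrades to a flagged bound.
- The eQTL scan assumes complete genotype rows per subject (the generator
  produces none missing); real data with missingness would need per-SNP
  complete-case handling inside the engine.
- `normality_and_transform` reports Shapiro–Wilk but never vetoes a
  transform; the transform choice is by measure type, with the screen kept
  as a diagnostic. Log-transforming ΔCt itself is deliberately avoided
  (ΔCt is already a log-scale quantity and can be negative); the linear
  relative expression is what gets the log10.
- The GGC caller needs the non-repeat amplicon base size as configuration;
  it is not inferable from fragment tables alone.
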