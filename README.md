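# relnxpress

Expression genetics of the reelin gene (*RELN*) in postmortem brain: a tested,
reusable pipeline for quantifying total and isoform-level *RELN* expression,
allelic-expression imbalance, and their association with candidate-region
genetic variation — driven end to end by a seeded synthetic-cohort generator.

## The scientific problem

Reelin is an extracellular-matrix glycoprotein central to neuronal migration
and synaptic plasticity; reduced *RELN* expression is one of the most-cited
molecular findings in schizophrenia and bipolar disorder. Two conserved
isoforms complicate the picture: a 6-nt **microexon** whose retention is
brain-specific, and an **alternative polyadenylation** site producing a short
transcript that lacks the C-terminal region. Whether disease is associated
with total expression, isoform balance, or allele-specific (*cis*-acting)
dysregulation requires four different measurements on the same donors:

- **qPCR ΔCt** — relative total expression against a reference gene (CHL1),
  and the short-isoform proportion 2^(Ct_total − Ct_polyA);
- **capillary peak heights** — microexon skipping as
  h_skipped / (h_skipped + h_retained), validated on a mixing series of two
  synthetic oligos;
- **allele-specific bead intensities** at the coding SNP rs2229864 — allelic
  expression imbalance (AEI) as |p_cDNA − p̂_expected|, where the expected
  balanced T-allele fraction is calibrated by regressing gDNA-heterozygote
  fractions on log10 signal intensity;
- **fragment-size genotyping** — an ApoI RFLP for the schizophrenia-associated
  intronic SNP rs7341475 (A: 233+158+30 bp, G: 233+188 bp) and a promoter GGC
  repeat (fragment = base + 3 bp × repeats).

Inference follows brain-bank practice: Shapiro–Wilk screening with log10
transforms, single-covariate confounder screens (pH, PMI, age, sex, brain
weight, age of onset), sequential-sums-of-squares ANOVA with the top
confounder entered first, a genotype-by-sex interaction model for rs7341475
(GG vs A-carrier), and a scan of 83 region SNPs filtered by exact
Hardy–Weinberg (P ≥ 0.05/83) and MAF > 5%, with family-wise correction by
**adaptive min-P permutation**: phenotypes are permuted until 20 permutation
minima beat the observed minimum P, and corrected P = 20 / N_permutations.

Real donor material of this kind is not publicly downloadable, so the package
ships a first-class synthetic generator (`relnxpress.synthio`) whose defaults
encode the study conditions — group sizes 35/32/35, polyA group means
8.7/6.0/8.5 %, retention ≈ 83.3 %, sex-by-genotype skipping cell means, an
intensity-dependent allelic bias, triplicate Ct noise — so every stage is
testable and calibratable without external data.

## Worked example

```python
from relnxpress import generate_bundle, qpcr, allelic

bundle = generate_bundle(seed=0)
expr = qpcr.quantify(bundle.ct).merge(bundle.subjects, on="subject_id")
print((100 * expr.groupby("diagnosis")["polya_proportion"].mean()).round(2))

aei_df, cal = allelic.run_aei(bundle.allele_signals,
                              bundle.genotypes["rs2229864"], bundle.subjects)
print(allelic.group_aei_summary(aei_df).round(3))
```

prints (seed 0):

```
diagnosis
BPD     6.30
CTRL    8.13
SCZ     8.70

diagnosis   n  mean_ratio  n_above_1.2  frac_above_1.2  n_above_1.4  frac_above_1.4
      BPD  12       1.163            4           0.333            0           0.000
     CTRL  17       1.092            1           0.059            1           0.059
      SCZ  18       1.335           12           0.667            7           0.389
```

The bipolar arm shows the configured deficit of the short isoform (6.3 % vs
8.1–8.7 %), and schizophrenia donors are far more likely to show allelic
ratios above 1.2 — the *cis*-dysregulation signature the AEI assay is built
to detect. The `examples/` directory holds one short script per capability
(simulation, qPCR, microexon validation, AEI, association scan, full run);
`reln-xpress run-all --workdir out --seed 42` runs everything from a shell
and writes a provenance-stamped `report.json`.

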