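# tp53axis

Case-control SNP association analysis for the p53 regulatory axis:
*TP53* rs1042522 (Arg72Pro), *MDM2* rs2279744 (309T>G), *MDM2* rs3730485
(del1518) and *MDM4* rs4245739 (34091 C>A) versus acute myeloid leukemia
(AML).

The package is aimed at genetic epidemiologists analysing a small panel of
candidate biallelic loci in a binary case-control design. It implements the
full analysis stack for such a study:

- **Genetic-model logistic regression** — each locus tested under the four
  standard inheritance codings of variant-allele dosage d ∈ {0, 1, 2}
  (codominant: dummies for d = 1 and d = 2; dominant: 1{d ≥ 1}; recessive:
  1{d = 2}; overdominant: 1{d = 1}), crude and adjusted for age group
  (≥ 60 y) and sex. Odds ratios and 95% CIs are Wald
  (OR = e^β, CI = e^{β ± 1.96·SE}); the per-coding model p-value is a
  likelihood-ratio test against the nested null; the four codings of a
  locus form one Benjamini–Hochberg FDR family.
- **Population genetics** — per-group Hardy–Weinberg χ² tests (1 df,
  expectations p², 2pq, q² from the estimated allele frequency) and
  two-locus linkage disequilibrium from unphased genotypes via EM, reporting
  D, |D′| = |D| / D_max, r² and a 1-df LRT for D = 0.
- **Pairwise epistasis matrices** — per coding, covariate-adjusted LRT
  p-values for the genotype × genotype interaction (upper triangle), the
  single-locus effect (diagonal), and the additive pair versus the best
  single-locus model (lower triangle).
- **MB-MDR** — model-based multifactor dimensionality reduction for binary
  traits, written from scratch: per-cell risk labelling (H if β > 0 and
  p < 0.10, L if β < 0 and p < 0.10, else O), merged-group Wald tests
  W = (β/SE)² adjusted for main effects and covariates, and a max(W_H, W_L)
  permutation correction.
- **Clinical categorical tests** — χ²/Fisher with automatic selection by
  the expected-count rule and BH-adjusted post-hoc contrasts.
- **Synthetic cohort generator** — because the study's individual-level
  genotypes are not deposited, a seeded generator reproduces its published
  statistical structure (403 cases / 406 controls, control-derived allele
  frequencies, |D′| ≈ 0.89 between the two *MDM2* loci, the observed *MDM4*
  HWE departure, and a logistic disease model with the published main-effect
  and interaction coefficients), so every stage is testable end to end.

## Worked example

```python
>>> from tp53axis import crude_or_from_counts, bh_adjust
>>> # recessive 2x2 from the published genotype counts:
>>> # 68/335 Pro/Pro vs other among cases, 37/369 among controls
>>> or_, ci, _ = crude_or_from_counts(68, 37, 335, 369)
>>> print(f"OR={or_:.2f}  95% CI=({ci[0]:.2f}, {ci[1]:.2f})")
OR=2.02  95% CI=(1.32, 3.10)
>>> bh_adjust([0.0003, 0.0009, 0.0020, 0.4960]).round(4)
array([0.0012, 0.0018, 0.0027, 0.496 ])
```

Pro/Pro homozygotes have twice the odds of AML of the other genotypes, and
the association survives FDR adjustment across the four codings.

The stochastic stages run on a synthetic replica of the study:

```python
>>> from tp53axis import (preset, simulate_cohort, em_haplotypes,
...                       permutation_correct)
>>> c = simulate_cohort(preset("study_replica", seed=1))
>>> (c.n_cases, c.n_controls)
(403, 406)
>>> est = em_haplotypes(c, "MDM2_rs2279744", "MDM2_rs3730485")
>>> print(f"|D'|={est.D_prime:.2f}  r2={est.r2:.2f}")
|D'|=0.91  r2=0.64
>>> res = permutation_correct(c, ("MDM2_rs2279744", "TP53_rs1042522"),
...                           n_perm=999, seed=42)
>>> print(f"N_H={res.n_h} N_L={res.n_l} W_L={res.w_l:.2f} "
...       f"perm_p={res.perm_p:.3f}")
N_H=1 N_L=1 W_L=14.05 perm_p=0.002
```

The EM estimate recovers the strong LD planted between the two *MDM2* loci,
and MB-MDR flags one high-risk and one low-risk two-locus genotype cell for
the rs2279744 × rs1042522 pair; the max-Wald permutation test (999
label shuffles) confirms the signal on this draw.

A command-line interface mirrors the library:

```sh
tp53axis simulate --preset study_replica --seed 1 --out cohort.tsv
tp53axis assoc   --table cohort.tsv --loci loci.yaml --out table1.tsv
tp53axis mbmdr   --table cohort.tsv --loci loci.yaml \
                 --orders 2,3,4 --n-perm 1000 --seed 42 --out table4.tsv
```

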