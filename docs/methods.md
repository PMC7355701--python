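# Methods

## Study design and data model

The package analyses a case-control cohort genotyped at four candidate
biallelic loci on the p53 regulatory axis. Genotypes are coded as the
dosage (0/1/2) of a configured *variant* allele; the orientation is fixed
by the locus configuration, never inferred from sample frequency, because
annotation conventions for these variants have changed between releases
(for the *MDM4* variant the current reference allele is C, so the
ancestral A allele is the counted one, matching the published genotype
tables). Covariates are binary: sex (male = 1) and age group (≥ 60 years).
Missing genotypes are handled complete-case per analysis; the motivating
study reports complete records, so this default only matters for user
data, and exclusions are logged.

## Per-locus association

For a coding with design columns X (one column, or two dummies for
codominant), the model is a maximum-likelihood binomial GLM with logit
link, `status ~ X (+ age_ge60 + sex)`. Per-level odds ratios and 95% CIs
are Wald (`z = 1.959964`); the single per-coding p-value is a
likelihood-ratio test against the nested null containing the same
covariates — 2 df for codominant, 1 df otherwise. The LRT was chosen over
an omnibus Wald because it reproduces the published per-coding p-values
exactly from the printed counts (e.g. 0.0003 / 0.4960 / 0.0009 / 0.0020
for the *TP53* locus, crude). For a one-column coding the GLM is a
saturated 2×2 model, so OR and CI coincide with the closed-form
cross-product estimator to numerical precision; the package asserts this
equivalence in tests. Zero cells in descriptive 2×2 tables get the
Haldane–Anscombe +0.5 correction with a flag; GLM degeneracies (empty
level, separation, non-convergence) are flagged and reported as NaN
p-values rather than corrected. The FDR family is the four codings of one
locus (crude and adjusted separately), Benjamini–Hochberg step-up.

The joint gene–gene model fits all four recessive-coded main effects, the
two biologically motivated product terms (rs2279744 × rs1042522 and
rs4245739 × rs3730485) and both covariates in a single logistic model.
Stratum odds ratios are derived as exp of summed coefficients — e.g. the
doubly-homozygous-variant stratum of the first pair is
exp(β_TP53 + β_interaction).

## Hardy–Weinberg and linkage disequilibrium

HWE uses the 1-df Pearson χ² against p², 2pq, q² expectations with the
allele frequency estimated from the same sample, no continuity correction
(this reproduces the published significance pattern from the printed
counts); a monomorphic sample returns χ² = 0, p = 1 by convention. An
exact test is not provided: the published p-values are unlabelled, and the
χ² choice is validated by reproducing them.

Two-locus haplotype frequencies come from an EM algorithm on the 3×3
unphased genotype table. Only the double heterozygote is phase-ambiguous;
the E-step splits it between the cis and trans resolutions in proportion
to f₀₀f₁₁ : f₀₁f₁₀. Initialisation is the independence solution (products
of allele frequencies), convergence when max |Δf| < 1e-8 (cap 1000
iterations; the fit is deterministic). The log-likelihood trace is stored
and asserted non-decreasing. D is reported between the two wild-type
alleles; |D′| = |D| / D_max with the usual frequency-dependent bound, and
significance is a 1-df LRT against the D = 0 distribution (allele
frequencies are fixed by the margins, so independence needs no refit).
When the double-heterozygote count is zero, EM converges in one step to
direct haplotype counting — an exact equivalence used as a test oracle.

## Pairwise epistasis matrices

For each coding the package reports a loci × loci matrix of LRT p-values,
all models containing the covariates: upper triangle — pair + product
term(s) vs additive pair (df = 1, or 4 for codominant; product columns
constant in the sample are dropped and the df reduced, flagged per cell);
diagonal — locus vs covariate-only; lower triangle — additive pair vs the
better (higher log-likelihood) single-locus model, ties broken by row
order. The published table's note describes the diagonal as the crude
effect while also stating all entries are covariate-adjusted; the
covariate-adjusted reading is implemented, making the diagonal identical
to the adjusted single-locus LRT.

## MB-MDR

Step 1 partitions subjects by their multi-locus genotype (codominant, up
to 3^k cells for a k-locus combination; k = 2–4) and tests each cell's
membership indicator against all other subjects. Unadjusted, this is a
saturated 2×2 logistic model, so the MLE is the closed-form log odds
ratio with Wald SE √(1/a + 1/b + 1/c + 1/d) — used directly, which makes
the permutation loop cheap. Cells are labelled H (β > 0, p < 0.10), L
(β < 0, p < 0.10) or O; the 0.10 threshold is the method's convention.
Cells with fewer than 5 subjects, or with a degenerate (all-case or
all-control) table, are forced to O and flagged; the source study states
no minimum, and 5 is a conservative floor below which the Wald statistic
is meaningless. A `step1_adjust`-style covariate-adjusted step 1 is not
default: the merged-group stage is where the published procedure applies
adjustment.

Step 2 merges the H cells and fits
`status ~ 1{H} + additive dosages of the combo's loci + age_ge60 + sex`,
reporting β_H, W_H = (β_H/SE)² and its 1-df χ² upper-tail p (likewise for
L); additive main-effect coding avoids the rank deficiency that full
codominant dummies plus the merged indicator would create. An empty
category yields NA, matching the published table's "Na" convention. The
combination's statistic is min(p_H, p_L).

The permutation correction shuffles case/control labels only (genotypes
and covariates stay with subjects), reruns both steps, and records
max(W_H, W_L), zero when both are NA. The corrected p-value uses the
add-one convention, (1 + #{perm ≥ obs}) / (n_perm + 1), so it never falls
below 1/(n_perm + 1). The published asymptotic p-values equal the
*uncorrected* χ²(1) tail of W at printed precision (verified for every
printed (W, p) pair), so no per-category Bonferroni is applied between W
and p; multiplicity control is the permutation test's job. Scans over all
combinations derive one child seed per combination from the master seed
(`SeedSequence(seed, spawn_key)`), so any row is reproducible in
isolation. Step-2 fits use an in-package IRLS Newton solver (needed to
keep 1000-permutation scans fast); the test suite verifies it against
statsmodels to 1e-6 on the same designs.

## Clinical categorical machinery

Omnibus r×c tests use Pearson χ² (no continuity correction — required to
reproduce the published sex-by-status p = 0.013) and switch to Fisher's
exact test when any expected count is below 5: exact for 2×2, seeded
Monte-Carlo over tables with fixed margins (probability ordering,
add-one estimator) otherwise. Post-hoc contrasts — each level vs the rest
by default, full pairwise optionally — are BH-adjusted within the family
of contrasts for that feature and attached when the omnibus p < 0.05 on a
table larger than 2×2.

## Synthetic cohort generator

The generator defines the study conditions used by all simulation-based
tests:

- **Group sizes** 403 cases / 406 controls.
- **Allele frequencies** computed from the published control genotype
  counts (variant frequencies ≈ 0.278, 0.410, 0.351, 0.655 at the TP53,
  MDM2-309, MDM2-del1518 and MDM4 loci).
- **LD**: the two *MDM2* loci are drawn as haplotype pairs; the default
  haplotype frequencies are the closed-form solution for |D′| = 0.89 at
  the control allele frequencies (D positive between the wild-type, and
  hence between the variant, alleles). `expected_ld` exposes the implied
  (D, D′, r²) so simulation output can be checked against the target.
- **HWE departure**: a per-locus inbreeding coefficient F distorts
  genotype probabilities to (1−f)q² + fq, (1−f)2pq, (1−f)p² + fp. The
  study offers no mechanism for its observed *MDM4* departure, so F is
  the minimal one-parameter emulator; the default F ≈ 0.38 is computed
  from the control heterozygote deficit.
- **Covariates** Bernoulli with control-group prevalences (male 0.446,
  age ≥ 60 0.544).
- **Disease model**: status ~ Bernoulli(expit(β₀ + Σ β·term)) with a small
  term language (`recessive(locus)`, `dominant(...)`, `overdominant(...)`,
  `additive(...)`, covariate names, `*`-products). The default β set is
  the study's joint recessive interaction model (−0.41, 0.51, 0.10, 0.26;
  interactions 1.22 and −0.92) plus covariate log-odds (0.35 male, −0.23
  age ≥ 60) derived from the published composition; β₀ = −1 keeps
  rejection sampling cheap. Because the generator uses the same codings as
  the analysis, the joint model is recoverable by construction.
- **Ascertainment** by rejection sampling from the population model until
  both quotas fill — exact under the logistic model at this scale; an
  attempt cap converts impossible quotas into a clear error.

Presets: `study_replica` (the default, above), `null` (no effects),
`interaction_gg_propro` (only the TP53 main effect and the first
interaction), and `observed_controls`, which draws every locus from the
published control genotype *proportions* directly (the del1518 control
distribution sits ~4% off HWE on the heterozygote class, so allele
frequencies alone cannot match it; the override is equivalent to an
allele frequency plus a per-locus F, at the cost of LD for the overridden
loci).

What the generator does **not** emulate: genuine retrospective
ascertainment bias beyond the logistic model, genotyping error, missing
data patterns, population stratification, clinical features (WBC, ELN
risk, …) and survival times. Passing simulation-based tests therefore
demonstrates correctness of the statistical machinery under the assumed
model, not robustness to those real-data complications.

## Numerical choices and problem sizes

- CI level fixed at 95% (z = 1.959964); GLM convergence tol 1e-8, max 100
  iterations; EM tol 1e-8 on frequencies; IRLS step tol 1e-10, |β| > 15
  treated as quasi-separation.
- Calibration and recovery experiments use desk-scale sizes chosen to
  keep the full suite in tens of seconds: type-I calibration at 100 seeds,
  n = 800, 200 permutations; coefficient recovery at 100 cohorts of
  n = 809; power at 50 seeds, 199 permutations; the KS uniformity check of
  the interaction LRT at n = 2000, where the rare recessive × recessive
  joint class is populated enough for the 1-df asymptotics.

## Known limitations

- The interaction coefficient of the replica model is estimated from a
  joint genotype class of roughly a dozen subjects at n = 809; the MLE
  shows visible finite-sample upward bias (median fitted β ≈ 1.6 for a
  planted 1.22) even though 95% CI coverage is nominal. This mirrors the
  wide published interval for that term (OR 3.38, CI 1.01–13.57).
- At the same scale the permutation-corrected two-order MB-MDR test has
  modest power (~1/3 of seeds significant at 0.05 under the replica
  model), consistent with the source study, where no two-order model
  survived permutation correction either — only three- and four-order
  combinations did.
- D′ between a haplotype-drawn locus and an independently drawn locus is
  zero by construction; only the *MDM2* pair carries LD.
- The EM estimator assumes HWE at the haplotype level within each group;
  strong inbreeding-type departures bias |D′| slightly upward.
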