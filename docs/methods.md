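# Methods

## Scope and data model

The package analyses a case-control cohort as a samples × variants dosage
matrix with entries in {0, 1, 2, missing} (count of the effect allele) and
a binary phenotype.  Non-SNP panel members — the ACE insertion/deletion
(D/I), the ENOS intron-4 VNTR (B/A) and the IL6 "14718" repeat (G/C) — are
coded as ordinary biallelic dosages of their effect allele, exactly as the
SNPs are; their published frequency tables use the same two-allele coding,
so nothing else is defensible without raw assay data.

The default 13-variant panel is a hard-coded fixture; every operation also
accepts user panels from TSV, so the machinery is not RPL-specific.  The
LD exclusion is rule-based (a flag in the panel), not computed from a
reference panel: the excluded IL10 SNP's LD partner is documented from
external population data, and recomputing r² is out of scope.  A panel
that has lost both IL10 SNPs is treated as malformed under the default
strict mode, since that is the one structural invariant the default panel
promises; `strict=False` disables the check for unrelated panels.

## Per-variant association

Log-additive logistic regression of case status on dosage, maximum
likelihood via Newton's method (statsmodels `Logit`, tolerance 1e-8 on the
score, 100 iterations max).  Inference is Wald throughout: SE from the
observed information, CI `exp(β ± z₀.₉₇₅·SE)`, two-sided normal p.  Wald
rather than profile-likelihood intervals because that is the
candidate-gene/GWAS default, and because sparse cells make the choice
visible: a variant with a handful of carrier alleles legitimately produces
an enormous upper CI bound under Wald, which is informative rather than a
bug.  No multiple-testing correction is applied; p-values are nominal and
presented as such.

Each variant is fit on its own complete cases (no imputation), so per-row
sample sizes differ when genotyping was staggered.  Fits are *flagged* —
status `constant_dosage`, `single_class` or `separation`, with NaN
numerics — rather than reported when no finite MLE exists.  Separation is
detected from the statsmodels separation guard plus a post-hoc check on
the fitted linear predictor (|η| > 15 after a non-converged or exploding
fit); at effect sizes that large the model has left the regime where Wald
numbers mean anything.  A genuinely non-converged fit inside the sane
region raises instead.

## The risk score

Raw score `Σ_j w_j d_ij` over genotyped variants; corrected score
`raw × M/m_i` with M = 12 (the post-exclusion panel size, never 13) and
`m_i ≥ 1` the per-person genotyped count.  The missing-dosage rule —
contribute zero and decrement `m` — is the only reading consistent with
that correction.  Samples with `m = 0` are excluded and reported, not
scored.  The correction is algebraically exact in the implementation
(`raw * M / m`, one expression), and tests assert bit-equality.

The score enters its logistic fit on the raw corrected scale: the OR is
per unit of corrected score.  Standardisation to per-SD units is available
(`standardize=True` / `--standardize`) but off by default, since the
headline estimates this package emulates are reported per score unit.

Weight schemes: `published_mixed` takes log(OR) from prior studies for
F2, F5, ESR1, ACE and MTHFR and in-study estimates for the other seven
(the published ENOS/IL6/IL10 estimates come from populations discordant
with the study sample, and F7/GP1A/ADRB2/IL8 have no prior estimate);
`study` takes every weight from the in-study per-variant fits; `unit`
weights every allele 1.  Two printed-table discordances are preserved as
printed rather than "fixed": the ESR1 and ACE published ORs are used on
the printed effect allele even though the in-study estimates for those
variants point the other way.  The panel TSV carries an explicit
`weight_rule` column (published/study/auto) because published-OR presence
alone cannot encode this rule.

## ROC analysis

Risk-score direction is fixed (case ⇔ score ≥ threshold; no auto-flip).
The empirical curve has a point per distinct score plus ±∞ sentinels;
trapezoidal AUC over this construction equals the Mann–Whitney estimator
with ties counted ½, an identity the tests verify against brute-force
pair counting.  The AUC interval is DeLong's placement-value
normal-approximation CI (the default of the standard ROC tooling in this
field), truncated to [0, 1]; degenerate placement variance collapses the
interval to the point with a warning.  A stratified percentile bootstrap
(2000 resamples) is available as an alternative.  The best discriminating
point maximises the Youden index with deterministic tie-breaking (higher
sensitivity, then lower threshold).

## Synthetic cohorts

`frequency_matched` mode draws each group's dosages independently as
Binomial(2, EAF_group) — Hardy–Weinberg within group — which reproduces a
printed case/control frequency table by construction.
`logistic_liability` mode draws genotypes at population EAFs and case
status from `logit P = intercept + β·d`, rejection-sampling to the target
group sizes (attempt cap: 100× the target n); under case-control sampling
the slope remains consistent while the intercept is biased, which is what
the parameter-recovery tests exploit.

Missingness is injected missing-completely-at-random within phenotype
group with *exact* per-variant genotyped quotas, previously missing cells
counting toward the quota; the generator guarantees every sample keeps at
least one genotyped variant (retrying the draw, then erroring).  MCAR
within group is the weakest assumption consistent with
enrolment/reagent-driven genotyping campaigns, which are plausibly
independent of genotype.

The study template (`replik_template_config`) fixes 114 cases / 106
controls, the printed 12 per-group EAFs, and the printed genotyped counts
(e.g. 75/46 for rs6046, 114/106 for rs1800896).

What the generator does **not** emulate, and what that means for the
tests: variants are independent (no LD — defensible because the scored
panel spans unlinked loci and its one LD pair was removed, but real
genomes are not this clean); missingness is independent *across people*,
whereas a real enrolment-driven campaign types people in blocks, so the
real per-person genotyped-count distribution is lumpier than the
simulated one.  The corrected score is sensitive to exactly that: the
M/m rescaling amplifies sampling noise for low-m people, so score-level
estimates from this generator are attenuated relative to a cohort with
block-structured missingness — most visibly for the unweighted score,
whose synthetic long-run OR sits near 1.0 where a real cohort with the
same marginal counts can print ~1.16.  Passing tests therefore
demonstrate the correctness of the estimators and their calibration
under the stated sampling model, not the field values of any particular
cohort.  There is no covariate (e.g. age) simulation; the emulated
models are unadjusted.

## Validation studies and problem sizes

- **Logistic oracle**: on random instances of ≤ 12 samples with a finite
  MLE, the Newton fit matches an exhaustive nested grid search of the
  log-likelihood (refined to 1e-4 resolution) to ≤ 1e-3; allele-flip
  equivariance (d → 2−d) holds to 1e-10.
- **AUC identity**: trapezoid = pair counting to 1e-10 on 100 random
  instances up to n ≈ 200, tied and untied.
- **DeLong**: frozen cross-check against an independent R pROC run on a
  fixed instance (agreement to 1e-10), plus a coverage study — 500
  frequency-matched replicates against the *exact* population AUC of the
  unit score obtained by convolving the group score distributions —
  requiring 0.95 ± 0.03.
- **Parameter recovery**: 200 liability replicates at 114/106, true
  per-allele slope 0.4, intercept −5.8 (baseline prevalence ≈ expit(−1) ≈
  0.27 so case quotas fill quickly); mean fitted slope within Monte-Carlo
  error of truth, Wald CI coverage 0.95 ± 0.03.
- **Null calibration**: 2000 equal-EAF replicates (EAF 0.5, 12 variants,
  114/106, full genotyping); pooled per-variant Wald rejection rate at
  α = 0.05 within 0.05 ± 0.01 and mean unit-GRS AUC within 0.50 ± 0.01.
  EAF 0.5 puts the test in the regime where Wald asymptotics apply; at
  the panel's rare-variant frequencies (~0.01–0.02) and n = 46 the Wald
  test is conservative and quasi-separation is common — a small-sample
  property of the statistic, not an implementation artifact, and the
  reason rare-variant fits can come back flagged.
- **Template fidelity**: per-variant genotyped counts are exact by
  construction; group EAFs averaged over 25 replicates sit within 4
  standard errors of the configured values.

The acceptance script runs the same machinery at slightly smaller sizes
(20 pipeline replicates, 500 null replicates, 100 recovery replicates),
chosen so a full from-scratch rerun stays in the tens of seconds while
Monte-Carlo error remains well below the effects of interest.  Template
replicates in which a rare variant is quasi-separated carry no in-study
weight for the `study` scheme and are skipped there; the JSON reports the
number of replicates actually used.

## Numerical conventions

Wald z is `Φ⁻¹(0.975) = 1.959963…`, not 1.96 rounded.  All randomness
flows from one integer seed through `numpy.random.SeedSequence`
substreams (pipeline stages get independent streams, so stages can be
re-run in isolation).  Tables are UTF-8 TSV, `NA` for missing, numbers at
`%.10g` plus display-rounded companion columns; identical seeds produce
byte-identical output files.

## Known limitations

- No LD-aware simulation or LD computation; the exclusion rule is
  declarative.
- No covariate adjustment and no exact (conditional) logistic regression
  for the sparse variants — their flagged fits are the honest output.
- The missingness correction rescales means but inflates the variance of
  low-m scores; alternatives (e.g. weighting by genotyped-variant
  information content) are out of scope.
- VCF import handles biallelic records with verbatim allele matching
  only; no strand flipping or liftover.
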