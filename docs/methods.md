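# Methods

This note documents the models, parameter choices, and numerical
conventions behind `pseudoscales`, and what the synthetic experiments do
and do not demonstrate.

## The comparator design

The quantity of interest is the effect of anticholinergic drug burden on a
binary outcome *beyond* the effect of taking many drugs. Because every
additional prescription has a non-trivial chance of being anticholinergic,
burden and polypharmacy are confounded by construction, and the usual
zero-effect null overstates any anticholinergic effect. The framework
replaces it with an empirical comparator: the distribution of effect
estimates across randomly constructed drug-burden scales (pseudoscales).
Two sampling pools distinguish *general* polypharmacy (all drugs) from
*anticholinergic* polypharmacy (drugs scored by at least one real burden
scale); two construction procedures give generic scales (across-sampling)
and scales matched to a specific ABS in size and potency multiset
(within-sampling).

## Synthetic cohort

Real primary-care linkage of this kind is access-restricted, so the
package generates a cohort with the same statistical skeleton, and —
crucially — a known data-generating model, which turns the framework's
qualitative claims into testable parameter-recovery statements.

**Formulary.** 525 drugs with long-tailed prescribing weights. The 214
anticholinergic-scored drugs form their own Zipf tail (exponent 1.3)
carrying 5% of total prescribing volume; the remaining 311 drugs follow a
Zipf(1.1) tail with the other 95%. The 5% share is what makes per-scale
user coverage land in the 10–45% range observed for real burden scales
(see *Pool asymmetry* below); anticholinergics are commonly prescribed but
are not the highest-volume drugs. Route profiles are drawn so that the
prescription-weighted expected fraction of ophthalmic/otic/nasal/topical
prescriptions is exactly 12.5%: a random ~15% of drugs are "local" products
(mostly non-systemic routes), the rest nearly always systemic, with
propensities rescaled to the target.

**Synthetic ABS registry.** 23 scales with sizes uniform on [15, 150].
Scale membership is drawn from the anticholinergic pool with probability
proportional to prescribing weight — mirroring the fact that the commonly
prescribed anticholinergics appear on most real scales — after a coverage
pass that guarantees every pool drug is scored by at least one scale.
Potency scores are i.i.d. from the across-sampling distribution
(0.017, 0.25, 0.20, 0.52, 0.009 for scores 4, 3, 2, 1, 0.5; the published
probabilities sum to 0.996 and are renormalized, treating the deficit as
rounding). The bundled registry and formulary are regenerated
deterministically from a fixed internal seed at import time; user-supplied
scale files in the same delimited format can replace them.

**Participants.** Age is Beta(1.9, 1.5) rescaled to [45, 80] (median
≈ 65.1); 55% female; graduate education 32%; ordinal lifestyle covariates
(alcohol 6 levels, smoking 3, physical activity 4) use frequencies close
to the descriptive statistics of the cohort being emulated; deprivation is
N(−2, 3²); waist N(90, 13²) cm; cerebrovascular disease has base
prevalence 3% rising with age (0.06 log-odds/year). Covariates are mutually
independent except where age enters explicitly — the emulated study reports
only marginals, so the joint distribution is a modelling choice.

**Prescriptions.** Annual counts are negative binomial (mean 12,
dispersion 1.5) with the mean increasing in age (2%/year) and multiplied
by an individual Gamma(2) morbidity frailty; drugs are drawn by
prescribing weight, routes from the drug's profile, dates uniformly over
the period. A 0.5% fraction of records is corrupted (empty content,
pre-birth, or future-dated) to exercise the cleaning stage, which removes
exactly those records.

**Outcomes.** For each outcome,
`logit P(event) = b0 + δ'C + βp·count + βa·trueburden`, with the true
burden computed under a designated generator-truth scale (the largest
bundled ABS by default). Defaults: βp = 0.01 per annual prescription and
βa = 0.1 per burden unit, chosen so per-SD pseudoscale ORs land in the
1.0–1.1 range reported for this design; prevalence targets are 6.2%
(death) and 1.6% (dementia, delirium). The baseline `b0` is calibrated by
bisection against the realized event indicator under common random
numbers: the achieved prevalence is a monotone step function of `b0`, so
the empirical rate matches the target to within 1/n rather than merely in
expectation. Follow-up times are generated for reporting only; time-to-
event models are out of scope.

## Analysis pipeline

Per (scale, outcome): complete-case filter → one-sided outlier removal
(values > mean + 4·SD of burden or residual polypharmacy; sample SD,
strict inequality, per-model so a participant is only dropped where they
are outlying) → standardization of numeric columns (sample SD, n−1) →
SMOTE → maximum-likelihood logistic fit (Newton). Residual polypharmacy
is annualized with the same divisor as burden for comparability; the
divisor is days/365.25, snapped to a whole number of years when within 1%
so a calendar year divides by exactly 1.

**SMOTE.** Classic synthetic minority oversampling: a synthetic point lies
uniformly on the segment between a random minority sample and one of its
k = 5 nearest minority neighbours (Euclidean distance on the standardized
design); binary/dummy columns copy the seed sample's values. The target
ratio defaults to 1.0 (full balance) — the emulated analysis does not
state its ratio, so it is configurable and recorded in the run manifest.
SMOTE trades p-value calibration for residual balance (synthetic rows are
treated as independent); the no-SMOTE variant is available as a
sensitivity switch, and the permutation-null type-I check in the test
suite runs without SMOTE for exactly this reason.

**Degenerate fits.** Binary covariates with a zero cell in the outcome
cross-tab are dropped before fitting (they produce quasi-separation);
fits that still fail (non-convergence, separation, unidentified SEs, or a
burden column that is constant after the 4-SD filter — common for sparse
scales in small cohorts) are flagged, excluded from summaries, and
counted in the manifest. On very sparse scales the 4-SD rule can remove
*every* nonzero burden value; this is a real property of the rule, not an
implementation artefact, and it disappears at realistic cohort sizes.

**Summaries.** Quantiles use linear interpolation (type 7) everywhere.
The rank-sum contrast uses exact enumeration for tie-free samples with
both sizes ≤ 20, otherwise the normal approximation with tie and
continuity corrections. The overlap coefficient integrates min(f̂, ĝ) by
the trapezoid rule on ≥ 2048 points spanning both samples ± 3 bandwidths,
with per-sample Gaussian KDEs. Bandwidths are Sheather–Jones
solve-the-equation plug-ins, computed with binned pairwise sums (1000
bins) and Brent root finding; the implementation is verified against R's
`stats::bw.SJ` to ≲ 0.1% on fixed samples. Pearson size–OR correlations
get Fisher-z 95% intervals. An ABS's *cumulative probability* is the
strictly-less-than fraction of matched pseudoscale ORs below its OR.

## Reproducibility

Every stage seed derives from sha256(master seed, stage name), so stages
are decoupled and each is a pure function of (inputs, stage seed);
identical configs give byte-identical summary reports. The run manifest
records the config hash, stage seeds, record counts, and non-convergence
counts. All outputs are delimited text or JSON.

## Problem sizes

The bundled experiments run on one CPU at reduced scale: machinery counts
and sampling-law checks use the full default scale construction (2000
across-sampling scales, 5750 within-sampling per pool — construction is
cheap); model-based parameter-recovery experiments use cohorts of
5,000–20,000 participants and 40–200 pseudoscales per pool, sizes at
which the rank-sum contrast between pools is already decisive. The
full study-scale configuration (200,000 participants, all three outcomes)
is expressible in `RunConfig` but is not exercised by the test suite.

## Known limitations

- **Pool asymmetry under the anticholinergic null.** With the outcome
  model linear in prescription count, a pseudoscale's true per-SD log-OR
  is approximately βp·SD(its on-scale prescription count), which grows
  with the prescribing volume the scale captures. General-pool scales can
  capture ~30% of volume, anticholinergic-pool scales at most ~5% (a
  direct consequence of the realistic 10–45% user-coverage condition).
  The two OR distributions therefore differ even when βa = 0 — the
  polypharmacy null is genuinely non-null, and it is not pool-invariant.
  This biases the general-vs-anticholinergic contrast *against* finding
  an anticholinergic effect (the anticholinergic pool starts from a
  weaker polypharmacy background), so the recovery of βa > 0 is
  conservative; but it also means a significant rank-sum contrast cannot,
  on its own, be read as proof of anticholinergic action. Comparisons of
  an ABS against its matched within-sampling null (same pool, same size)
  do not suffer from this asymmetry.
- Covariate correlations beyond age effects are not modelled; the
  confounding structure is deliberately simple (age → prescribing volume
  and age → risk).
- No drug–drug interactions, dosage, adherence, or incident/prevalent
  user distinction; scores are per prescription event, not per dose.
- Passing parameter-recovery tests on this generator shows the pipeline
  measures what it claims under the stated model; it cannot certify
  behaviour under real-world confounding by indication or healthcare
  utilization.
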