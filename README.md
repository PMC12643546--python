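# pseudoscales

Anticholinergic drugs and polypharmacy travel together: patients prescribed
many drugs are, almost mechanically, prescribed more anticholinergic drugs.
Any association between an anticholinergic burden scale (ABS) score and an
outcome such as death, dementia, or delirium therefore mixes a putative
anticholinergic effect with the background effect of simply taking many
drugs. Testing a burden score against the usual zero-effect null cannot
separate the two.

`pseudoscales` implements a simulation framework that replaces the zero
null with a **polypharmacy null**: randomly constructed drug-burden scales
("pseudoscales") with no pharmacological rationale. Each pseudoscale scores
a random set of drugs with random potencies; the distribution of its effect
estimates measures what drug *quantity alone* produces. A real ABS exhibits
an anticholinergic effect beyond polypharmacy only if it beats this
distribution. The package targets pharmacoepidemiologists and methods
researchers who want to study or extend this comparator design without
access to restricted primary-care data: a synthetic cohort generator with a
*known* data-generating model stands in for the real records, so the
framework's ability to recover a true anticholinergic effect can be checked
exactly.

## Model

For participant *i* and scale *s*, the annual cumulative burden is

    B_is = (1 / T) * Σ_j  w_s(d_j)

summing over *i*'s in-period prescriptions *j*, where `w_s(d)` is the
potency score of drug *d* under scale *s* (0.5–4; 0 if off-scale or given
by an ophthalmic, otic, nasal, or topical route) and *T* is the period
length in years. Each (scale, outcome) pair is analysed with logistic
regression

    logit P(Y_i = 1) = α + β·z(B_is) + γ·z(B0_is) + δ'C_i

where `z(·)` standardizes, `B0_is` is residual polypharmacy (annualized
count of prescriptions for drugs *off* scale *s*), and `C_i` are
confounders (age, sex, provider, education, deprivation, alcohol, waist,
smoking, physical activity, cerebrovascular disease). Minority outcomes are
rebalanced with SMOTE before fitting; burden and residual-polypharmacy
values more than 4 SD above the mean are removed. `exp(β)` is the odds
ratio per 1 SD of burden.

Pseudoscales come in two flavours:

- **across-sampling** — scale size uniform on [15, 150], drugs drawn
  without replacement from a pool (all 525 formulary drugs, or only the
  214 scored anticholinergic by ≥1 ABS), potencies drawn with
  probabilities 0.017/0.25/0.20/0.52/0.009 for scores 4/3/2/1/0.5
  (renormalized); 1000 scales per pool.
- **within-sampling** — matched to one template ABS: identical size and
  potency multiset, 250 replicates per ABS per pool (5750 per pool).

Per outcome and pool, the package reports 95% simulation intervals, median
and IQR of the ORs, the Wilcoxon rank-sum contrast between pools, the
overlap coefficient ∫ min(f̂, ĝ) of the two OR densities (Gaussian KDE,
Sheather–Jones bandwidths), the fraction of significantly positive
associations, the Pearson correlation of OR with scale size, and each
ABS's cumulative probability within its matched within-sampling null.

## Worked example

```python
import numpy as np
from pseudoscales import *
from pseudoscales.burden_scoring import burden_table
from pseudoscales.outcome_models import results_frame

formulary, registry = default_formulary(), default_registry()
pools = {"general": {d.drug_id for d in formulary},
         "anticholinergic": anticholinergic_pool(registry, formulary)}

participants = generate_participants(20_000, seed=1)
rx = generate_prescriptions(participants, formulary, seed=2)
rx, n_removed = clean_prescriptions(rx, participants)
truth = max(registry.abs_scales(), key=lambda s: s.size)
outcomes = generate_outcomes(participants, rx,
    EffectConfig(prevalence_targets={"death": 0.062}), seed=3, truth_scale=truth)

scales = []
for i, name in enumerate(("general", "anticholinergic")):
    scales += sample_across(pools[name],
        SamplingConfig(pool=name, n_scales=100, seed=10 + i))
table = burden_table(rx, scales, ("2015-01-01", "2015-12-31"),
                     participants["participant_id"])
res = results_frame(run_scale_models(scales, table, participants, outcomes,
                                     ModelConfig(seed=4)))
res = res[res.converged]
gen = res.loc[res.pool == "general", "or_per_sd"]
ant = res.loc[res.pool == "anticholinergic", "or_per_sd"]
print(f"death prevalence {outcomes.loc[outcomes.outcome=='death','event'].mean():.1%}, "
      f"{n_removed} corrupt records removed")
print(f"general         median OR {gen.median():.3f}  95% SI {np.percentile(gen,2.5):.3f}-{np.percentile(gen,97.5):.3f}")
print(f"anticholinergic median OR {ant.median():.3f}  95% SI {np.percentile(ant,2.5):.3f}-{np.percentile(ant,97.5):.3f}")
print(f"rank-sum p = {rank_sum_test(gen, ant):.1e}   overlap = {kde_overlap(gen, ant):.2f}")
```

prints (about 20 s on one CPU):

```
death prevalence 6.2%, 1225 corrupt records removed
general         median OR 1.019  95% SI 0.931-1.117
anticholinergic median OR 1.064  95% SI 0.996-1.119
rank-sum p = 2.1e-12   overlap = 0.55
```

The cohort here carries a true anticholinergic effect (0.1 log-odds per
unit of burden under the designated generator-truth scale) on top of a
polypharmacy effect (0.01 log-odds per annual prescription). Pseudoscales
built from the anticholinergic pool partially capture the true burden and
shift right of the general-polypharmacy null — the qualitative signature
the framework is designed to detect — while the general pool's median near
1.02 shows the non-zero background that a naive zero-null comparison would
misattribute to anticholinergic action.

The same run is available as a CLI:

```sh
pseudoscales run-all --smoke --seed 2 --out runs/demo     # seconds-scale demo
pseudoscales run-all --config my_config.yaml --out runs/full
```

Each stage (`simulate-data`, `sample-scales`, `score`, `fit`, `summarize`)
can also be re-run standalone on a run directory.

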