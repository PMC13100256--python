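# pacsurv

Association versus prediction for **pulmonary artery compliance (PAC)**
on right-heart-catheterization (RHC) cohorts.

PAC = SV / PP (stroke volume over pulmonary pulse pressure, mL/mmHg)
measures the pulsatile component of right-ventricular afterload, the
counterpart of the steady-state pulmonary vascular resistance
PVR = (mPAP − PAWP) / CO (Wood units). The two are physically tethered
by the resistance–compliance time constant, RC = PAC × PVR ≈ 0.3–0.7 s,
which makes PAC and PVR tightly, inversely, hyperbolically related. The
statistical consequence is the question this package operationalizes:
a variable can be strongly *associated* with mortality yet add nothing
to mortality *prediction* once its correlated companions are in the
model. Association and prediction are different questions requiring
different machinery, and `pacsurv` implements both sides:

1. **Association stage** — Cox proportional-hazards models of
   all-cause mortality with a linear-tail restricted cubic spline
   (4 knots) in PAC, hazard-ratio curves relative to a reference PAC of
   3 mL/mmHg, adjusted dichotomized hazard ratios (low = PAC < 3) in
   hemodynamic subgroups (PAWP ≤/> 15 mmHg, PVR ≤/> 2.2 WU), and a
   sensitivity analysis restricted to pulmonary hypertension
   (mPAP > 20 mmHg).
2. **Prediction stage** — Monte Carlo cross-validation: repeatedly
   sample 2000 subjects, split 1500 train / 500 test, fit a full Cox
   model (age, gender, race, body size, Charlson index, atrial
   fibrillation, OSA, hypertension, mPAP, PAC) and "handicapped"
   variants with one variable removed, and compare the hold-out
   Harrell's C distributions by ANOVA, paired contrasts, and a Bayesian
   estimate of the paired mean ΔC with a region of practical
   equivalence (ROPE) at |ΔC| < 0.01.

Because real catheterization registries are not redistributable, the
package ships a seeded synthetic cohort generator that reproduces the
structure the analyses rely on — realistic marginals, the RC coupling
between PAC and PVR, and proportional-hazards survival with
user-specified effects — including a *redundancy scenario* in which PAC
is correlated with the hazard drivers but conditionally null: the
exact construction under which "associated but not predictive" is the
right answer.

The statistical kernel (Cox partial likelihood with Efron/Breslow
ties, Harrell's concordance under censoring, Harrell-form restricted
cubic splines, Grambsch–Therneau proportional-hazards diagnostic) is
implemented from scratch in `pacsurv.survival` and is verified in the
test suite against literal pair enumeration, brute-force likelihood
grid search, and lifelines.

## Worked example

```python
from pacsurv.synthetic import GeneratorConfig, make_redundancy_scenario
from pacsurv.association import dichotomized_hr
from pacsurv.prediction import MCCVConfig, run_mccv, compare_models

cohort = make_redundancy_scenario(GeneratorConfig(seed=1))
est = dichotomized_hr(cohort)                      # adjusted low-vs-high PAC
comp = compare_models(run_mccv(cohort, MCCVConfig(seed=1)))
```

prints (via the obvious format calls):

```
cohort: n=12866, deaths=5464, median PAC=2.65 mL/mmHg
low vs high PAC (adjusted): HR 1.32 [1.25-1.39], p=3.5e-23, n=12866
minus_age   dC=+0.0506  p=1.2e-49   ROPE mass=0.00
minus_mpap  dC=+0.0254  p=3.76e-39  ROPE mass=0.00
minus_pac   dC=-0.0003  p=0.024     ROPE mass=1.00
```

Read it as the two halves of the story. Low PAC carries a strongly
significant adjusted hazard ratio of 1.32 — PAC is *associated* with
mortality — even though, by construction, PAC has zero conditional
effect in this cohort (the hazard depends only on age and mPAP; PAC
inherits its association through the RC coupling). Yet removing PAC
from the predictive model changes mean hold-out concordance by
−0.0003, with the entire posterior of the difference inside the
±0.01 region of practical equivalence: PAC adds no *predictive* value.
Removing age or mPAP, the true drivers, costs 0.051 and 0.025 of C
with overwhelming significance. Note the PAC row's paired-t p = 0.024:
with 100 repetitions sharing subjects, nominal p-values resolve
differences far below practical relevance — which is exactly why the
ROPE mass, not the p-value, carries the equivalence claim.

## Command line

```sh
pacsurv generate --seed 1 --outdir runs          # synthetic cohort only
pacsurv predict --seed 1 --outdir runs           # full pipeline
pacsurv report runs/run_<stamp>_<hash>           # summarize a run
```

Each invocation writes a fresh timestamped run directory with the
cohort, QC audit, association curve/HR tables, per-repetition C-index
table, comparison summary, and a `provenance.json` carrying the config
hash, seeds, per-stage row counts, and failure counts. A YAML config
(`--config`) can override the generator marginals, effects, adjustment
set, and MCCV sizes, or point the pipeline at an existing cohort table
(`input_cohort` + `column_map`).

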