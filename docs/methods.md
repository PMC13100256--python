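# Methods

This note records the models, assumptions, parameter choices and
numerical policies behind `pacsurv`, and what the synthetic-data
checks do and do not demonstrate about real catheterization data.

## Hemodynamic derivation, QC, and PH classification

Five derived quantities per record: PP = sPAP − dPAP,
TPG = mPAP − PAWP, PVR = TPG/CO (Wood units), SV = 1000·CO/HR (mL; the
factor 1000 converts CO from L/min so that PAC = SV/PP lands in
mL/mmHg), PAC = SV/PP. A non-positive pulse pressure leaves PAC
*flagged undefined* rather than infinite or NaN: downstream stages
must confront the flag, never silently inherit a propagated value.
dPAP ≤ mPAP ≤ sPAP is deliberately not assumed; real tracings violate
it and QC reports rather than repairs.

Physiologic-range QC uses strict inequalities throughout — a value
exactly on a bound passes: CO outside (0.5, 15) L/min, mPAP outside
(5, 80), dPAP outside (0, 70), sPAP outside (7, 130), PAWP outside
(0, 60) mmHg, HR outside (10, 200) bpm, age outside (18, 90) years.
Exclusion counting is consort-style first-reason-wins in a fixed
documented order (age → date error → prior transplant/VAD →
hemodynamic ranges), so per-reason counts sum to the number excluded.

PH classification follows the 2022 ESC/ERS hemodynamic rules: no PH
iff mPAP ≤ 20 mmHg; within PH, pre-capillary (PAWP ≤ 15, PVR > 2 WU),
isolated post-capillary (PAWP > 15, PVR ≤ 2), combined (PAWP > 15,
PVR > 2), and "undetermined" for the remaining corner
(PAWP ≤ 15, PVR ≤ 2). The five labels partition the space of complete
triples; records with a missing component are reported separately,
not guessed.

## Survival kernel

**Cox fitting.** Newton maximization of the log partial likelihood,
Efron tie correction by default (Breslow available). Covariate columns
are centered internally — the partial likelihood is shift-invariant,
so coefficients are unchanged while `exp` overflow is avoided.
Convergence requires max |score| < 1e-8 within 50 iterations;
step-halving (cap 25) guards non-concave steps, and decreases within
1e-9·(|ℓ|+1) are treated as floating-point noise rather than halved
forever. Constant and exactly collinear columns are rejected up front
with the offending names (QR rank check, relative tolerance 1e-9).
Monotone-likelihood separation is flagged by a standardized-coefficient
guard (|β|·sd(x) > 10 ⇒ not converged): a separated fit is returned
explicitly as non-converged, never raised or silently accepted.
Standard errors and 95% CIs are Wald on the log-hazard scale.

**Concordance.** Harrell's C with higher score = higher risk. A pair
is comparable iff the smaller observed time belongs to an event; at a
shared time an event is treated as preceding a censored observation,
and two events at the same time are not comparable. Score ties count
0.5. The implementation is vectorized; the test suite pins it,
field-by-field, to a literal O(n²) enumeration on a thousand random
censored datasets.

**Restricted cubic splines.** Harrell's truncated-power form with
4 knots: one linear plus two nonlinear columns, each nonlinear column
vanishing at and below the first knot and the whole function exactly
linear beyond the boundary knots. Default knot placement is the
conventional (0.05, 0.35, 0.65, 0.95) quantiles of the exposure,
overridable. The hazard-ratio curve is the contrast against the
reference exposure (PAC 3 mL/mmHg by default), so HR ≡ 1 with a
zero-width band at the reference by construction, with a delta-method
pointwise 95% band elsewhere.

**PH diagnostic.** Grambsch–Therneau score test on Schoenfeld
residuals against a transform of event time; the default transform is
the Kaplan–Meier scale g(t) = 1 − KM(t−), robust to long follow-up
tails ("identity" and "rank" available). Per-covariate χ²(1) and a
global χ²(p) are reported. Datasets with fewer than two events are
declined with an explicit message.

## Synthetic cohort generator

The generator emulates the joint structure the analyses exploit, not
any particular registry's microdata.

**Marginals** (defaults; every one overridable in `GeneratorConfig`):
age ~ Normal(63.5, 13.3) truncated to QC range; male 55%; race
white/black/unknown/other at 84/10/5/1%; BMI lognormal(median 28,
log-sd 0.258); BSA ~ Normal(1.9, 0.25) m²; Charlson index
~ Poisson(2.5); atrial fibrillation 26%, hypertension 68%, OSA 17%;
HR ~ Normal(76, 17); mPAP lognormal(median 28, log-sd 0.44);
CO lognormal(median 4.9, log-sd 0.383). These families are matched to
the medians and IQR ratios typical of adult RHC referral populations;
only medians/quartiles constrain them, so the family choices are
calibration approximations, not ground truth.

**Coupling.** PAWP is a Beta-distributed fraction of mPAP (mean 0.53,
sd 0.16), which keeps TPG positive by construction and ties PVR to
mPAP the way mixed pre-/post-capillary physiology does. The RC time
τ is lognormal with median 0.40 s (log-sd 0.25) and
PAC = τ/(0.06·PVR) — the unit identity 1 WU = 0.06 mmHg·s/mL — which
produces the inverse hyperbolic PAC–PVR relation and, through mPAP's
role in PVR, a Pearson correlation of about −0.4 between PAC and
mPAP. Pressures are reconstructed around mPAP from the implied pulse
pressure with the classical split mPAP = dPAP + PP/3 (configurable
`pp_split`). Rows violating QC ranges or dPAP > 0 are rejected and
redrawn (rejection count reported; > 99% rejection raises as an
infeasible config). Derived PAC from the emitted raw pressures equals
the intended PAC to ~1e-9 relative — the round-trip the unit tests
pin.

With these defaults the generated medians land near PAC 2.6 mL/mmHg,
PVR 2.5 WU, PAWP 14, sPAP 45, dPAP 18 mmHg, and the PH-subgroup mix is
roughly 31% combined post/pre-capillary, 26% pre-capillary, 22% no PH,
14% isolated post-capillary, 6% undetermined.

**Survival.** Proportional hazards with a Weibull baseline: cumulative
hazard (t/scale)^shape with shape 1.1 and scale 22 years, sampled by
inverse transform, T = scale·(E·e^(−lp))^(1/shape), E ~ Exp(1). The
linear predictor sums named effects on covariate transforms (identity,
log, below-threshold indicator) and is centered so the baseline
controls the marginal event fraction (~40% by the 15-year horizon,
typical of referral RHC cohorts). Censoring is independent:
min(administrative horizon 15 y, a Uniform(0, horizon) dropout time
applied to a 30% dropout fraction). Default effects are 0.03/yr on age
and 0.025/mmHg on mPAP with *no* PAC term — the redundancy scenario:
PAC is correlated with the drivers through the RC coupling yet
conditionally null, so the correct verdict is "associated but not
predictive".

**What passing tests do and do not show.** Covariates other than the
PAWP–mPAP–PAC chain are sampled independently; there is no measurement
error, no informative censoring, no competing risks, no dPAP
underestimation from motion artifact, and exact proportional hazards
by construction. Tests passing here demonstrate that the machinery
recovers known truths under its own assumptions — not that any real
registry satisfies those assumptions.

## Association stage

Adjustment set: age, gender, race, body size, Charlson index, atrial
fibrillation, OSA, hypertension. The body-size term is configurable
with BMI as default (BSA selectable) — clinical reports are
inconsistent about which is used, and the choice is surfaced rather
than buried. Reference covariate values (mode for categorical/binary,
median for continuous) label the adjusted curve but cancel exactly in
the contrast, so they never affect the plotted HR. Dichotomization
uses low = PAC < 3 mL/mmHg with the boundary counted high (boundary
conventions differ across reports; this one is documented and
configurable). Subgroup models are refit per subgroup (the simplest
reading of subgroup tables; interaction-term models are the noted
alternative). A subgroup with fewer than 2 events in either PAC arm is
declined with a message rather than estimated. The PH-only sensitivity
analysis restricts to mPAP > 20 mmHg and re-runs both operations.

## Prediction stage

Per repetition: 2000 subjects sampled *without* replacement within the
repetition, independently re-drawn across the 100 repetitions
(subjects recur across repetitions); 1500/500 train/test; the full
model and every handicapped variant (refit with the variable removed,
not coefficient-zeroed) share the identical partition, so all
contrasts are paired by repetition. The master seed spawns one child
seed per repetition; reruns are exactly reproducible. Failed
repetitions (non-convergence, or a test set with no comparable pairs)
are excluded and counted, never imputed.

**Comparison.** Omnibus one-way ANOVA across variants and a paired t
per handicap are both reported and labeled distinctly. Caveat, stated
once and relied on throughout: MCCV repetitions share subjects, so
these nominal p-values are approximate and, for the paired contrast,
anti-conservative — with 100 paired repetitions a systematic ΔC of a
few 1e-4 (practically nothing) can reach p < 0.05. That is why the
practical-equivalence claim is carried by the Bayesian estimate: the
per-repetition paired differences are modeled as Student-t(ν = 4, μ,
σ) with weakly-informative priors μ ~ Normal(0, 0.05) and
σ ~ HalfNormal(0.05) (both on the C-index scale, where differences of
interest are ~0.01), and the posterior is integrated on a
deterministic 2-D (μ, log σ) grid — no sampler, no Monte Carlo error.
Reported: posterior mean, 95% highest-density interval, and the mass
inside the ROPE |μ| < 0.01. The ROPE bound of 0.01 encodes the
judgment that a concordance change below one point in the second
decimal cannot alter clinical ranking decisions.

**Subgroups.** MCCV + comparison re-run within PH classes or PVR bins
(≤2, (2,3], (3,5], >5 WU; boundaries to the lower bin, documented).
Strata smaller than the sample size shrink proportionally — 5/6 of the
stratum rounded down to a multiple of 4, keeping the 3:1 train:test
ratio (e.g., a 120-row stratum samples 100, split 75/25) — with a
logged note; strata below 40 samples are skipped with a message.

## Problem sizes used in the checks

The shipped checks run the kernel oracles at n ≤ 60 (concordance,
1000 datasets) and n ≤ 30 (likelihood grid search, 100 datasets);
parameter recovery at n = 5000 × 200 replicates; the redundancy
pattern at the full default protocol (cohort 12,866; 100 repetitions
of 1500/500) once for the equivalence claim and across 50 outer seeds
for the significance claim; and end-to-end determinism on two complete
default-configuration runs. These sizes were chosen so the entire
verification cycle completes comfortably on a single CPU while keeping
every protocol parameter at its default value.

## Known limitations

* The generator's covariance structure is minimal by design: race,
  gender and comorbidities are independent of hemodynamics, which is
  adequate for the recovery/redundancy properties but not for studying
  confounding by those variables.
* No competing risks, time-varying covariates, stratified baselines,
  or alternative survival learners; the framework is concordance-only
  by scope.
* The Charlson index is consumed as an integer; computing it from
  administrative codes is out of scope.
* Cause-specific mortality and exercise hemodynamics are not modeled.
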