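"""Synthetic right-heart-catheterization cohort generator.

Emulates the statistical structure the downstream analyses assume:

* covariate and hemodynamic marginals calibrated to a referral RHC
  population (medians/IQRs of age, BMI, CCI, HR, mPAP, PAWP, CO and
  comorbidity prevalences);
* the resistance–compliance coupling PAC = τ / (0.06 · PVR), where the
  RC time τ is lognormal — this produces the inverse hyperbolic
  PAC–PVR relation seen in real hemodynamics (1 Wood unit =
  0.06 mmHg·s/mL);
* systolic/diastolic PA pressures reconstructed around mPAP from the
  implied pulse pressure using the classical mPAP ≈ dPAP + PP/3 split;
* proportional-hazards survival with user-set log-hazard effects on
  covariate transforms, a Weibull baseline sampled by inverse
  transform, and independent censoring (administrative horizon plus
  uniform dropout).

Every draw is governed by a single integer seed; identical config +
seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .hemodynamics import AGE_RANGE_YEARS, PHYSIOLOGIC_RANGES, classify_table, derive_table

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "generate_hemodynamics",
    "generate_survival",
    "generate_cohort",
    "make_redundancy_scenario",
    "WOOD_UNIT_SECONDS",
]

#: 1 Wood unit expressed in mmHg·s/mL (mmHg·min/L × 60 s / 1000 mL).
WOOD_UNIT_SECONDS = 0.06


@dataclass(frozen=True)
class EffectSpec:
    """One named log-hazard effect on a covariate transform.

    ``transform``: "identity", "log", or "below_threshold" (an
    indicator of column < threshold, e.g. PAC < 3 mL/mmHg).
    """

    column: str
    coefficient: float
    transform: str = "identity"
    threshold: Optional[float] = None

    def apply(self, cohort: pd.DataFrame) -> np.ndarray:
        if self.column not in cohort.columns:
            raise ValueError(f"effect references unknown column {self.column!r}")
        x = cohort[self.column].to_numpy(float)
        if self.transform == "identity":
            v = x
        elif self.transform == "log":
            if np.any(x <= 0):
                raise ValueError(f"log transform of non-positive column {self.column!r}")
            v = np.log(x)
        elif self.transform == "below_threshold":
            if self.threshold is None:
                raise ValueError("below_threshold transform requires a threshold")
            v = (x < self.threshold).astype(float)
        else:
            raise ValueError(f"unknown transform {self.transform!r}")
        return self.coefficient * v


def _default_marginals() -> dict:
    """Marginal specs calibrated so generated medians/IQRs land near a
    typical adult RHC referral population (see docs/methods.md)."""
    return {
        "age": {"dist": "normal", "mean": 63.5, "sd": 13.3},
        "male": {"dist": "bernoulli", "p": 0.55},
        "race": {
            "dist": "categorical",
            "levels": ["white", "black", "unknown", "other"],
            "p": [0.84, 0.10, 0.05, 0.01],
        },
        "bmi": {"dist": "lognormal", "median": 28.0, "logsd": 0.258},
        "bsa": {"dist": "normal", "mean": 1.9, "sd": 0.25},
        "cci": {"dist": "poisson", "lam": 2.5},
        "afib": {"dist": "bernoulli", "p": 0.26},
        "htn": {"dist": "bernoulli", "p": 0.68},
        "osa": {"dist": "bernoulli", "p": 0.17},
        "heart_rate": {"dist": "normal", "mean": 76.0, "sd": 17.0},
        "mpap": {"dist": "lognormal", "median": 28.0, "logsd": 0.44},
        # wedge pressure as a Beta-distributed fraction of mPAP: keeps
        # TPG positive by construction and couples PVR to mPAP the way
        # real pre/post-capillary physiology does
        "pawp": {"dist": "mpap_fraction", "mean": 0.53, "sd": 0.16},
        "cardiac_output": {"dist": "lognormal", "median": 4.9, "logsd": 0.383},
    }


def _default_effects() -> tuple[EffectSpec, ...]:
    # age and mPAP drive the hazard; PAC carries no conditional effect
    # (it is correlated with the hazard only through the RC coupling).
    return (
        EffectSpec("age", 0.03, "identity"),
        EffectSpec("mpap", 0.025, "identity"),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort.

    ``rc_time_mean`` is the median RC time τ in seconds (lognormal with
    log-sd ``rc_time_logsd``); ``pp_split`` is the fraction of pulse
    pressure placed above mPAP (2/3 reproduces mPAP ≈ dPAP + PP/3).
    ``baseline_shape``/``baseline_scale`` parametrize the Weibull
    baseline cumulative hazard (t/scale)^shape (scale in years);
    censoring is min(administrative ``censoring_horizon``, a
    Uniform(0, horizon) dropout applied to a ``dropout_rate`` fraction
    of subjects).
    """

    n: int = 12866
    seed: int = 0
    marginals: dict = field(default_factory=_default_marginals)
    rc_time_mean: float = 0.40
    rc_time_logsd: float = 0.25
    pp_split: float = 2.0 / 3.0
    coefficients: tuple[EffectSpec, ...] = field(default_factory=_default_effects)
    baseline_shape: float = 1.1
    baseline_scale: float = 22.0
    censoring_horizon: float = 15.0
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rc_time_mean <= 0:
            raise ValueError("rc_time_mean must be positive")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline shape and scale must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        for key, spec in self.marginals.items():
            if spec.get("dist") == "bernoulli" and not 0.0 <= spec["p"] <= 1.0:
                raise ValueError(f"prevalence for {key!r} outside [0, 1]")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _draw(rng: np.random.Generator, spec: dict, n: int):
    dist = spec["dist"]
    if dist == "normal":
        return rng.normal(spec["mean"], spec["sd"], n)
    if dist == "lognormal":
        return np.exp(rng.normal(np.log(spec["median"]), spec["logsd"], n))
    if dist == "bernoulli":
        return (rng.random(n) < spec["p"]).astype(int)
    if dist == "categorical":
        return rng.choice(spec["levels"], size=n, p=spec["p"])
    if dist == "poisson":
        return rng.poisson(spec["lam"], n)
    raise ValueError(f"unknown marginal distribution {dist!r}")


def _in_range(values: np.ndarray, key: str) -> np.ndarray:
    lo, hi, _ = PHYSIOLOGIC_RANGES[key]
    return (values >= lo) & (values <= hi)


def generate_hemodynamics(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw covariates and raw + derived hemodynamics for ``config.n``
    subjects.

    Rows violating physiologic-range QC, non-positive TPG, or
    non-positive dPAP are rejected and redrawn (so the emitted cohort
    passes its own QC by construction); the rejection count is reported
    in ``DataFrame.attrs["n_rejected"]``.  A rejection rate above 99%
    marks the config infeasible and raises.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.marginals
    accepted: list[pd.DataFrame] = []
    n_accepted = 0
    n_rejected = 0
    n_drawn = 0
    while n_accepted < config.n:
        batch = max(config.n - n_accepted, 256)
        batch = int(batch * 1.5)
        df = pd.DataFrame(index=range(batch))
        for key in (
            "age", "male", "race", "bmi", "bsa", "cci", "afib", "htn", "osa",
            "heart_rate", "mpap", "pawp", "cardiac_output",
        ):
            spec = m[key]
            if spec.get("dist") == "mpap_fraction":
                mean, sd = spec["mean"], spec["sd"]
                conc = mean * (1 - mean) / sd**2 - 1.0
                if conc <= 0:
                    raise ValueError("mpap_fraction spec implies non-Beta variance")
                frac = rng.beta(mean * conc, (1 - mean) * conc, batch)
                df[key] = frac * df["mpap"].to_numpy()
            else:
                df[key] = _draw(rng, spec, batch)
        tau = np.exp(rng.normal(np.log(config.rc_time_mean), config.rc_time_logsd, batch))

        tpg = df["mpap"].to_numpy() - df["pawp"].to_numpy()
        co = df["cardiac_output"].to_numpy()
        hr = df["heart_rate"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            pvr = tpg / co
            pac = tau / (WOOD_UNIT_SECONDS * pvr)
            sv = 1000.0 * co / hr
            pp = sv / pac
        spap = df["mpap"].to_numpy() + config.pp_split * pp
        dpap = df["mpap"].to_numpy() - (1.0 - config.pp_split) * pp
        df["spap"] = spap
        df["dpap"] = dpap
        df["intended_pac"] = pac
        df["rc_time"] = tau

        lo_a, hi_a = AGE_RANGE_YEARS
        ok = (
            (tpg > 0)
            & (dpap > 0)
            & (df["age"].to_numpy() >= lo_a) & (df["age"].to_numpy() <= hi_a)
            & (df["bmi"].to_numpy() > 10) & (df["bsa"].to_numpy() > 1.0)
            & _in_range(co, "cardiac_output")
            & _in_range(df["mpap"].to_numpy(), "mpap")
            & _in_range(dpap, "dpap")
            & _in_range(spap, "spap")
            & _in_range(df["pawp"].to_numpy(), "pawp")
            & _in_range(hr, "heart_rate")
        )
        n_drawn += batch
        n_rejected += int((~ok).sum())
        kept = df.loc[ok]
        accepted.append(kept)
        n_accepted += len(kept)
        if n_drawn >= max(10 * config.n, 2000) and n_accepted < 0.01 * n_drawn:
            raise ValueError(
                f"infeasible generator config: rejection rate "
                f"{1 - n_accepted / n_drawn:.3f} exceeds 0.99"
            )
    out = pd.concat(accepted, ignore_index=True).iloc[: config.n].reset_index(drop=True)
    out = derive_table(out)
    out["ph_class"] = classify_table(out)
    out.attrs["n_rejected"] = n_rejected
    return out


def generate_survival(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Attach proportional-hazards event times and independent
    censoring to a generated cohort.

    The linear predictor sums the configured effects and is centered
    (mean zero) so the baseline scale controls the marginal event
    fraction regardless of effect settings; the centered value is
    stored as ``true_lp``.  Event times come from the Weibull baseline
    via inverse-transform sampling: T = scale·(E·e^{−lp})^{1/shape}
    with E ~ Exp(1).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n = len(cohort)
    out = cohort.copy()
    lp = np.zeros(n)
    for eff in config.coefficients:
        lp = lp + eff.apply(out)
    lp = lp - lp.mean()

    E = rng.exponential(1.0, n)
    T = config.baseline_scale * (E * np.exp(-lp)) ** (1.0 / config.baseline_shape)

    cens = np.full(n, config.censoring_horizon)
    drop = rng.random(n) < config.dropout_rate
    dropout_time = rng.uniform(0.0, config.censoring_horizon, n)
    cens = np.where(drop, np.minimum(cens, dropout_time), cens)

    time = np.minimum(T, cens)
    event = (T <= cens).astype(int)
    # follow-up must be strictly positive for the partial likelihood
    time = np.maximum(time, 1e-8)
    out["time"] = time
    out["event"] = event
    out["true_lp"] = lp
    out.attrs.update(cohort.attrs)
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Hemodynamics + survival in one deterministic call."""
    hemo = generate_hemodynamics(config)
    return generate_survival(hemo, config)


def make_redundancy_scenario(config: Optional[GeneratorConfig] = None) -> pd.DataFrame:
    """Cohort in which PAC is correlated with the hazard drivers but
    conditionally null.

    The hazard depends only on age and mPAP; PAC is tied to mPAP/PVR
    through the RC coupling (negatively correlated with both) yet has a
    true conditional effect of exactly zero.  This is the construction
    on which "associated but not predictive" rests: any apparent
    predictive value of PAC here is borrowed from mPAP.
    """
    if config is None:
        config = GeneratorConfig()
    config = config.replace(coefficients=_default_effects())
    cohort = generate_cohort(config)
    cohort.attrs["scenario"] = "redundancy"
    cohort.attrs["true_pac_effect"] = 0.0
    return cohort
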