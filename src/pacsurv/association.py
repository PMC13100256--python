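"""Association analysis: spline hazard-ratio curves for PAC, adjusted
dichotomized hazard ratios in hemodynamic subgroups, and the PH-only
sensitivity analysis.

The adjustment set is age, gender, race, a body-size term (BMI by
default, BSA selectable), CCI, atrial fibrillation, OSA and
hypertension.  Curves are expressed relative to a reference PAC
(default 3 mL/mmHg, HR ≡ 1 there); the adjusted curve is a contrast
within one fitted model, so the covariate reference values (mode for
categorical, median for continuous) cancel exactly and only label the
curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .survival import CoxFit, SplineSpec, default_knots, fit_cox, rcs_basis

__all__ = [
    "HazardRatioEstimate",
    "HRCurve",
    "ADJUSTMENT_COVARIATES",
    "SUBGROUP_FILTERS",
    "build_covariate_design",
    "spline_hr_curve",
    "dichotomized_hr",
    "ph_only_sensitivity",
]

ADJUSTMENT_COVARIATES = ("age", "male", "race", "body_size", "cci", "afib", "osa", "htn")

#: Documented subgroup filters: PAWP cut at 15 mmHg, PVR cut at 2.2 WU.
SUBGROUP_FILTERS = {
    "pawp_low": lambda df: df["pawp"] <= 15,
    "pawp_high": lambda df: df["pawp"] > 15,
    "pvr_low": lambda df: df["pvr"] <= 2.2,
    "pvr_high": lambda df: df["pvr"] > 2.2,
}


@dataclass(frozen=True)
class HazardRatioEstimate:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    subgroup_label: str
    log_hr: float
    se: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


@dataclass
class HRCurve:
    grid: np.ndarray  # PAC values
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    adjusted: bool
    reference_pac: float
    fit: CoxFit
    reference_covariates: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pac": self.grid, "hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high}
        )


def build_covariate_design(
    cohort: pd.DataFrame, body_size: str = "bmi"
) -> pd.DataFrame:
    """Numeric adjustment design: age, male indicator, race dummies
    (white = baseline), the chosen body-size column, CCI and the three
    comorbidity indicators."""
    if body_size not in ("bmi", "bsa"):
        raise ValueError(f"body_size must be 'bmi' or 'bsa', got {body_size!r}")
    design = pd.DataFrame(index=cohort.index)
    design["age"] = cohort["age"].astype(float)
    design["male"] = cohort["male"].astype(float)
    race = cohort["race"].astype(str)
    for level in ("black", "unknown", "other"):
        design[f"race_{level}"] = (race == level).astype(float)
    design[body_size] = cohort[body_size].astype(float)
    design["cci"] = cohort["cci"].astype(float)
    for col in ("afib", "osa", "htn"):
        design[col] = cohort[col].astype(float)
    return design


def _reference_covariates(design: pd.DataFrame) -> dict:
    """Mode for binary/dummy columns, median for continuous ones."""
    ref = {}
    for col in design.columns:
        vals = design[col]
        if set(np.unique(vals)) <= {0.0, 1.0}:
            ref[col] = float(vals.mode().iloc[0])
        else:
            ref[col] = float(vals.median())
    return ref


def _complete_rows(cohort: pd.DataFrame, cols) -> pd.DataFrame:
    sub = cohort.dropna(subset=[c for c in cols if c in cohort.columns])
    return sub


def spline_hr_curve(
    cohort: pd.DataFrame,
    adjusted: bool,
    spec: Optional[SplineSpec] = None,
    grid: Optional[np.ndarray] = None,
    body_size: str = "bmi",
    ties: str = "efron",
) -> HRCurve:
    """Continuous PAC–mortality hazard-ratio curve from a restricted
    cubic spline Cox model.

    The curve is exp(contrast versus the reference PAC), with a
    pointwise 95% delta-method band; HR is exactly 1 (band width 0) at
    the reference.  Raises if the reference lies outside the observed
    PAC range.
    """
    needed = ["pac", "time", "event"]
    if adjusted:
        needed += ["age", "male", "race", body_size, "cci", "afib", "osa", "htn"]
    data = _complete_rows(cohort, needed)
    pac = data["pac"].to_numpy(float)
    if spec is None:
        spec = SplineSpec(knots=default_knots(pac), reference=3.0)
    if not (pac.min() <= spec.reference <= pac.max()):
        raise ValueError(
            f"reference PAC {spec.reference} outside observed range "
            f"[{pac.min():.3g}, {pac.max():.3g}]"
        )

    basis = rcs_basis(pac, spec)
    spline_names = [f"pac_rcs{j}" for j in range(basis.shape[1])]
    X = pd.DataFrame(basis, columns=spline_names, index=data.index)
    ref_cov: dict = {}
    if adjusted:
        cov = build_covariate_design(data, body_size=body_size)
        ref_cov = _reference_covariates(cov)
        X = pd.concat([X, cov], axis=1)
    fit = fit_cox(X, data["time"], data["event"], ties=ties)

    if grid is None:
        lo, hi = np.quantile(pac, [0.01, 0.99])
        grid = np.linspace(lo, hi, 200)
    grid = np.asarray(grid, float)
    b_grid = rcs_basis(grid, spec)
    b_ref = rcs_basis(np.array([spec.reference]), spec)
    contrast = np.zeros((len(grid), len(fit.coefficients)))
    contrast[:, : b_grid.shape[1]] = b_grid - b_ref
    log_hr = contrast @ fit.coefficients
    var = np.einsum("gi,ij,gj->g", contrast, fit.covariance, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.975)
    return HRCurve(
        grid=grid,
        hr=np.exp(log_hr),
        ci_low=np.exp(log_hr - z * se),
        ci_high=np.exp(log_hr + z * se),
        adjusted=adjusted,
        reference_pac=spec.reference,
        fit=fit,
        reference_covariates=ref_cov,
    )


def dichotomized_hr(
    cohort: pd.DataFrame,
    threshold: float = 3.0,
    subgroup: Optional[str] = None,
    orientation: str = "low_vs_high",
    body_size: str = "bmi",
    ties: str = "efron",
) -> HazardRatioEstimate:
    """Adjusted Cox hazard ratio for dichotomized PAC.

    ``low`` is PAC < threshold (the boundary value counts as high).
    ``orientation`` labels the reported ratio: ``"low_vs_high"`` is the
    hazard of low relative to high PAC; ``"high_vs_low"`` its exact
    reciprocal.  ``subgroup`` restricts to one of
    :data:`SUBGROUP_FILTERS`; the model is refit within the subgroup.
    Declines (raises) when either PAC arm has fewer than 2 events.
    """
    if orientation not in ("low_vs_high", "high_vs_low"):
        raise ValueError(f"unknown orientation {orientation!r}")
    label = "all"
    data = _complete_rows(
        cohort, ["pac", "time", "event", "age", "male", "race", body_size,
                 "cci", "afib", "osa", "htn"]
    )
    if subgroup is not None:
        if subgroup not in SUBGROUP_FILTERS:
            raise ValueError(
                f"unknown subgroup {subgroup!r}; choose from {sorted(SUBGROUP_FILTERS)}"
            )
        data = data.loc[SUBGROUP_FILTERS[subgroup](data)]
        label = subgroup

    low = (data["pac"] < threshold).astype(float)
    ev = data["event"].astype(int)
    ev_low = int(ev[low == 1].sum())
    ev_high = int(ev[low == 0].sum())
    if ev_low < 2 or ev_high < 2:
        raise ValueError(
            f"subgroup {label!r} declined: <2 events in a PAC arm "
            f"(low={ev_low}, high={ev_high})"
        )

    X = build_covariate_design(data, body_size=body_size)
    X.insert(0, "pac_low", low)
    fit = fit_cox(X, data["time"], data["event"], ties=ties)
    beta = fit.coefficients[0]
    se = fit.standard_errors[0]
    if orientation == "high_vs_low":
        beta = -beta
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return HazardRatioEstimate(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(p),
        n=len(data),
        n_events=int(ev.sum()),
        subgroup_label=f"{label}:{orientation}",
        log_hr=float(beta),
        se=float(se),
    )


def ph_only_sensitivity(
    cohort: pd.DataFrame,
    threshold: float = 3.0,
    spec: Optional[SplineSpec] = None,
    body_size: str = "bmi",
) -> dict:
    """Re-run the association analyses restricted to subjects with
    pulmonary hypertension (mPAP > 20 mmHg).

    Drops exactly the NO_PH rows; raises when the restriction leaves an
    empty cohort.  Results are labeled ``ph_only``.
    """
    restricted = cohort.loc[cohort["mpap"].astype(float) > 20]
    if restricted.empty:
        raise ValueError("PH-only sensitivity: no subjects with mPAP > 20 mmHg")
    out = {
        "label": "ph_only",
        "n": len(restricted),
        "curve": spline_hr_curve(restricted, adjusted=True, spec=spec, body_size=body_size),
        "dichotomized": dichotomized_hr(restricted, threshold=threshold, body_size=body_size),
    }
    return out
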