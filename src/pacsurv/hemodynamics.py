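"""Derived right-heart-catheterization hemodynamics, physiologic-range QC,
cohort exclusions, and hemodynamic pulmonary-hypertension classification.

Five derived quantities per record:

    PP  = sPAP - dPAP          (pulse pressure, mmHg)
    TPG = mPAP - PAWP          (transpulmonary gradient, mmHg)
    PVR = TPG / CO             (pulmonary vascular resistance, Wood units)
    SV  = 1000 * CO / HR       (stroke volume, mL)
    PAC = SV / PP              (pulmonary artery compliance, mL/mmHg)

PH subgroups follow the 2022 ESC/ERS hemodynamic rules: PH requires
mPAP > 20 mmHg; within PH, pre-capillary (PAWP <= 15, PVR > 2 WU),
isolated post-capillary (PAWP > 15, PVR <= 2 WU), combined post- and
pre-capillary (PAWP > 15, PVR > 2 WU), and "undetermined" for the
remaining combination (PAWP <= 15, PVR <= 2 WU).

QC never repairs data: physiologically impossible values and
non-positive pulse pressures are flagged, not fixed or NaN-propagated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RHCMeasurement",
    "DerivedHemodynamics",
    "QCCode",
    "QCResult",
    "PHClass",
    "ExclusionAudit",
    "derive_hemodynamics",
    "check_physiologic",
    "classify_ph",
    "apply_exclusions",
    "derive_table",
    "classify_table",
    "PHYSIOLOGIC_RANGES",
    "AGE_RANGE_YEARS",
    "EXCLUSION_ORDER",
]


class QCCode(str, enum.Enum):
    """Enumerated exclusion / quality-control reason codes."""

    CO_RANGE = "CO_RANGE"
    MPAP_RANGE = "MPAP_RANGE"
    DPAP_RANGE = "DPAP_RANGE"
    SPAP_RANGE = "SPAP_RANGE"
    PAWP_RANGE = "PAWP_RANGE"
    HR_RANGE = "HR_RANGE"
    AGE_RANGE = "AGE_RANGE"
    DATE_ERROR = "DATE_ERROR"
    PRIOR_TX_VAD = "PRIOR_TX_VAD"
    NONPOSITIVE_PP = "NONPOSITIVE_PP"


#: Strict physiologic bounds (low, high): a value fails iff value < low or
#: value > high.  Boundary values pass.
PHYSIOLOGIC_RANGES: dict[str, tuple[float, float, QCCode]] = {
    "cardiac_output": (0.5, 15.0, QCCode.CO_RANGE),
    "mpap": (5.0, 80.0, QCCode.MPAP_RANGE),
    "dpap": (0.0, 70.0, QCCode.DPAP_RANGE),
    "spap": (7.0, 130.0, QCCode.SPAP_RANGE),
    "pawp": (0.0, 60.0, QCCode.PAWP_RANGE),
    "heart_rate": (10.0, 200.0, QCCode.HR_RANGE),
}

#: Adults only: age < 18 or > 90 years is excluded (strict bounds).
AGE_RANGE_YEARS: tuple[float, float] = (18.0, 90.0)

#: First-reason-wins order for consort-style exclusion counting.
EXCLUSION_ORDER: tuple[QCCode, ...] = (
    QCCode.AGE_RANGE,
    QCCode.DATE_ERROR,
    QCCode.PRIOR_TX_VAD,
    QCCode.CO_RANGE,
    QCCode.MPAP_RANGE,
    QCCode.DPAP_RANGE,
    QCCode.SPAP_RANGE,
    QCCode.PAWP_RANGE,
    QCCode.HR_RANGE,
)


@dataclass(frozen=True)
class RHCMeasurement:
    """Raw pressures and flows from one right heart catheterization.

    dpap <= mpap <= spap is *not* assumed: real tracings violate it and
    QC flags rather than silently reorders.  ``rap`` is carried but not
    used by any derived quantity.
    """

    heart_rate: float  # beats/min
    spap: float  # mmHg
    dpap: float  # mmHg
    mpap: float  # mmHg
    pawp: float  # mmHg
    cardiac_output: float  # L/min
    rap: Optional[float] = None  # mmHg, optional


@dataclass(frozen=True)
class DerivedHemodynamics:
    """The five calculated hemodynamic variables for one record.

    ``pac`` is None (and ``pac_undefined`` True) when pulse pressure is
    non-positive; the other quantities are still reported.
    """

    pp: float  # mmHg
    tpg: float  # mmHg
    pvr: float  # Wood units
    sv: float  # mL
    pac: Optional[float]  # mL/mmHg
    pac_undefined: bool = False


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason_codes: tuple[QCCode, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reason_codes) == 0):
            raise ValueError("passed must be equivalent to empty reason_codes")


class PHClass(str, enum.Enum):
    NO_PH = "NO_PH"
    PRECAP = "PRECAP"
    IPCPH = "IPCPH"
    CPCPH = "CPCPH"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class ExclusionAudit:
    """Consort-style audit: per-reason counts in the documented order."""

    counts: dict[QCCode, int] = field(
        default_factory=lambda: {code: 0 for code in EXCLUSION_ORDER}
    )
    n_input: int = 0
    n_retained: int = 0

    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": [c.value for c in EXCLUSION_ORDER],
                "n_excluded": [self.counts[c] for c in EXCLUSION_ORDER],
            }
        )


def derive_hemodynamics(m: RHCMeasurement) -> DerivedHemodynamics:
    """Compute PP, TPG, PVR, SV and PAC from a raw measurement.

    SV is reported in mL: CO in L/min is converted via the factor 1000.
    Raises ``ValueError`` for non-positive heart rate or cardiac output;
    a non-positive pulse pressure flags PAC as undefined rather than
    propagating an infinity.
    """
    if not np.isfinite(m.heart_rate) or m.heart_rate <= 0:
        raise ValueError(f"heart_rate must be positive, got {m.heart_rate}")
    if not np.isfinite(m.cardiac_output) or m.cardiac_output <= 0:
        raise ValueError(f"cardiac_output must be positive, got {m.cardiac_output}")

    pp = m.spap - m.dpap
    tpg = m.mpap - m.pawp
    pvr = tpg / m.cardiac_output
    sv = 1000.0 * m.cardiac_output / m.heart_rate
    if pp <= 0:
        return DerivedHemodynamics(
            pp=pp, tpg=tpg, pvr=pvr, sv=sv, pac=None, pac_undefined=True
        )
    return DerivedHemodynamics(pp=pp, tpg=tpg, pvr=pvr, sv=sv, pac=sv / pp)


def check_physiologic(m: RHCMeasurement, age: Optional[float] = None) -> QCResult:
    """Flag out-of-range hemodynamics and out-of-range age.

    All bounds are strict as a matter of policy (a value exactly on a
    bound passes).  Missing (None/NaN) fields yield no range code; QC
    reports and never raises.
    """
    codes: list[QCCode] = []
    if age is not None and np.isfinite(age):
        lo, hi = AGE_RANGE_YEARS
        if age < lo or age > hi:
            codes.append(QCCode.AGE_RANGE)
    for attr, (lo, hi, code) in PHYSIOLOGIC_RANGES.items():
        value = getattr(m, attr)
        if value is None or not np.isfinite(value):
            continue
        if value < lo or value > hi:
            codes.append(code)
    return QCResult(passed=not codes, reason_codes=tuple(codes))


def classify_ph(mpap: float, pawp: float, pvr: float) -> PHClass:
    """Assign the ESC/ERS hemodynamic PH subgroup for one complete triple.

    The five labels partition (mpap, pawp, pvr) space; records with a
    missing component raise rather than being silently dropped.
    """
    for name, v in (("mpap", mpap), ("pawp", pawp), ("pvr", pvr)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"classify_ph requires finite {name}, got {v}")
    if mpap <= 20:
        return PHClass.NO_PH
    if pawp <= 15 and pvr > 2:
        return PHClass.PRECAP
    if pawp > 15 and pvr <= 2:
        return PHClass.IPCPH
    if pawp > 15 and pvr > 2:
        return PHClass.CPCPH
    return PHClass.UNDETERMINED


# ---------------------------------------------------------------------------
# Vectorized table operations
# ---------------------------------------------------------------------------

#: Columns a cohort table must provide for QC / derivation.
MEASUREMENT_COLUMNS = ("heart_rate", "spap", "dpap", "mpap", "pawp", "cardiac_output")


def derive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived-hemodynamics columns (pp, tpg, pvr, sv, pac,
    pac_undefined) to a cohort table.  Vectorized version of
    :func:`derive_hemodynamics`; rows with non-positive HR/CO get NaN
    derived values plus an invalid flag instead of raising."""
    out = cohort.copy()
    hr = out["heart_rate"].to_numpy(float)
    co = out["cardiac_output"].to_numpy(float)
    valid = np.isfinite(hr) & (hr > 0) & np.isfinite(co) & (co > 0)

    pp = out["spap"].to_numpy(float) - out["dpap"].to_numpy(float)
    tpg = out["mpap"].to_numpy(float) - out["pawp"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvr = np.where(valid, tpg / co, np.nan)
        sv = np.where(valid, 1000.0 * co / hr, np.nan)
        pac = np.where(valid & (pp > 0), sv / pp, np.nan)

    out["pp"] = pp
    out["tpg"] = tpg
    out["pvr"] = pvr
    out["sv"] = sv
    out["pac"] = pac
    out["pac_undefined"] = valid & (pp <= 0)
    out["invalid_measurement"] = ~valid
    return out


def classify_table(cohort: pd.DataFrame) -> pd.Series:
    """PH subgroup label per row; rows with an incomplete (mpap, pawp,
    pvr) triple get the sentinel ``"MISSING"`` and are reported, not
    classified."""
    mpap = cohort["mpap"].to_numpy(float)
    pawp = cohort["pawp"].to_numpy(float)
    pvr = cohort["pvr"].to_numpy(float)
    complete = np.isfinite(mpap) & np.isfinite(pawp) & np.isfinite(pvr)

    label = np.full(len(cohort), "MISSING", dtype=object)
    no_ph = complete & (mpap <= 20)
    precap = complete & (mpap > 20) & (pawp <= 15) & (pvr > 2)
    ipcph = complete & (mpap > 20) & (pawp > 15) & (pvr <= 2)
    cpcph = complete & (mpap > 20) & (pawp > 15) & (pvr > 2)
    undet = complete & (mpap > 20) & (pawp <= 15) & (pvr <= 2)
    label[no_ph] = PHClass.NO_PH.value
    label[precap] = PHClass.PRECAP.value
    label[ipcph] = PHClass.IPCPH.value
    label[cpcph] = PHClass.CPCPH.value
    label[undet] = PHClass.UNDETERMINED.value
    return pd.Series(label, index=cohort.index, name="ph_class")


def _row_first_reason(row: pd.Series) -> Optional[QCCode]:
    """First applicable exclusion reason in the documented order."""
    age = row.get("age", None)
    if age is not None and np.isfinite(age):
        lo, hi = AGE_RANGE_YEARS
        if age < lo or age > hi:
            return QCCode.AGE_RANGE
    if bool(row.get("date_error", False)):
        return QCCode.DATE_ERROR
    if bool(row.get("prior_tx_vad", False)):
        return QCCode.PRIOR_TX_VAD
    for attr, (lo, hi, code) in PHYSIOLOGIC_RANGES.items():
        value = row.get(attr, None)
        if value is None or not np.isfinite(value):
            continue
        if value < lo or value > hi:
            return code
    return None


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Filter a cohort by age, date-error, prior-transplant/VAD, and
    physiologic-range rules; return the retained rows and a
    consort-style audit.

    A row excludable for several reasons is counted once, under the
    first applicable reason in :data:`EXCLUSION_ORDER`.  An empty output
    cohort raises, since every downstream stage needs data.
    """
    audit = ExclusionAudit(n_input=len(cohort))
    reasons = cohort.apply(_row_first_reason, axis=1)
    keep = reasons.isna()
    for code in reasons[~keep]:
        audit.counts[code] += 1
    retained = cohort.loc[keep].copy()
    audit.n_retained = len(retained)
    if retained.empty:
        raise ValueError("all rows excluded: empty cohort after QC")
    return retained, audit
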