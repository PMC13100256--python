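"""Survival-analysis kernel: Cox partial-likelihood fitting, Harrell's
concordance index under right censoring, restricted cubic spline bases,
and a Schoenfeld-residual proportional-hazards diagnostic.

Pure in-memory numerics — no file I/O.  All tolerances and defaults are
surfaced on :class:`CoxSettings`.

The Cox fitter maximizes the log partial likelihood by Newton iteration
with step-halving, supporting the Efron (default) and Breslow tie
corrections.  The partial likelihood is invariant to shifting covariate
columns, so columns are centered internally for numerical stability;
reported coefficients are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CoxSettings",
    "CoxFit",
    "ConcordanceResult",
    "SplineSpec",
    "fit_cox",
    "predict_risk",
    "harrell_c",
    "rcs_basis",
    "default_knots",
    "ph_diagnostic",
    "kaplan_meier",
]


@dataclass(frozen=True)
class CoxSettings:
    """Numerical policy for :func:`fit_cox`.

    ``tol`` is on the maximum absolute score (gradient) component;
    ``max_iter`` caps Newton iterations; ``max_halvings`` caps
    step-halving within one iteration.
    """

    tol: float = 1e-8
    max_iter: int = 50
    max_halvings: int = 25
    collinearity_rtol: float = 1e-9


@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``coefficients`` are log hazard ratios; ``covariance`` is the
    inverse observed information (symmetric PSD at the optimum).
    ``converged`` is False for separated / non-converging fits — such a
    result is returned explicitly, never silently.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    n_iterations: int
    converged: bool
    ties_method: str
    names: tuple[str, ...]
    n: int
    n_events: int
    _center: np.ndarray = field(repr=False, default=None)

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def confidence_intervals(self, level: float = 0.95) -> np.ndarray:
        """Wald CI for the hazard ratios, computed on the log scale."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.column_stack([lo, hi])

    def p_values(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    comparable_pairs: int
    concordant: int
    tied_score: int


@dataclass(frozen=True)
class SplineSpec:
    """Knots and reference point for a restricted cubic spline of an
    exposure (here: PAC on the mL/mmHg axis, reference where HR = 1)."""

    knots: tuple[float, float, float, float]
    reference: float = 3.0

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, float)
        if len(k) != 4:
            raise ValueError("SplineSpec requires exactly 4 knots")
        if np.any(np.diff(k) <= 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------


def _validate_design(X: np.ndarray, names: Sequence[str], rtol: float) -> None:
    """Reject constant and exactly collinear columns, naming offenders."""
    sd = X.std(axis=0)
    scale = np.abs(X).max(axis=0)
    const = sd <= rtol * np.maximum(scale, 1.0)
    if const.any():
        bad = [names[j] for j in np.flatnonzero(const)]
        raise ValueError(f"constant covariate column(s): {bad}")
    Xc = X - X.mean(axis=0)
    # QR-based rank check; a tiny diagonal flags the dependent column
    _, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    dep = diag <= rtol * max(diag.max(), 1.0)
    if dep.any():
        bad = [names[j] for j in np.flatnonzero(dep)]
        raise ValueError(f"exactly collinear covariate column(s): {bad}")


# ---------------------------------------------------------------------------
# Partial likelihood machinery
# ---------------------------------------------------------------------------


def _cox_quantities(
    Xs: np.ndarray,
    event: np.ndarray,
    start: np.ndarray,
    beta: np.ndarray,
    ties: str,
    want_hessian: bool = True,
):
    """Log partial likelihood, score, and observed information for
    time-sorted data.

    ``Xs``/``event`` are sorted ascending by time; ``start`` holds the
    first index of each tied-time block.  Risk-set sums are suffix
    cumulative sums; blocks with a single event share a fast fully
    vectorized path (Efron and Breslow coincide there), while multi-event
    blocks loop to apply the chosen tie correction.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # invariant shift; guards exp overflow
    w = np.exp(eta)
    wX = w[:, None] * Xs

    S0s = np.cumsum(w[::-1])[::-1]
    S1s = np.cumsum(wX[::-1], axis=0)[::-1]
    if want_hessian:
        wXX = wX[:, :, None] * Xs[:, None, :]
        S2s = np.cumsum(wXX[::-1], axis=0)[::-1]

    d = np.add.reduceat(event.astype(float), start)
    ev_blocks = np.flatnonzero(d > 0)
    e_f = event.astype(float)

    loglik = float(np.sum(e_f * eta))
    grad = (e_f[:, None] * Xs).sum(axis=0)
    hess = np.zeros((p, p)) if want_hessian else None

    single = ev_blocks[d[ev_blocks] == 1]
    if single.size:
        idx = start[single]
        phi = S0s[idx]
        mu = S1s[idx] / phi[:, None]
        loglik -= float(np.sum(np.log(phi)))
        grad -= mu.sum(axis=0)
        if want_hessian:
            hess += np.einsum("gij,g->ij", S2s[idx], 1.0 / phi)
            hess -= np.einsum("gi,gj->ij", mu, mu)

    multi = ev_blocks[d[ev_blocks] > 1]
    if multi.size:
        s0 = np.add.reduceat(w * e_f, start)
        s1 = np.add.reduceat(wX * e_f[:, None], start, axis=0)
        if want_hessian:
            s2e = wXX * e_f[:, None, None]
        for g in multi:
            dg = int(d[g])
            i0 = start[g]
            S0_b, S1_b = S0s[i0], S1s[i0]
            if want_hessian:
                S2_b = S2s[i0]
                i1 = start[g + 1] if g + 1 < len(start) else n
                s2_b = s2e[i0:i1].sum(axis=0)
            if ties == "breslow":
                fracs = np.zeros(dg)
            else:  # efron
                fracs = np.arange(dg) / dg
            for f in fracs:
                phi = S0_b - f * s0[g]
                M1 = S1_b - f * s1[g]
                mu = M1 / phi
                loglik -= float(np.log(phi))
                grad -= mu
                if want_hessian:
                    M2 = S2_b - f * s2_b
                    hess += M2 / phi - np.outer(mu, mu)
    return loglik, grad, hess


def fit_cox(
    X,
    time,
    event,
    ties: str = "efron",
    names: Optional[Sequence[str]] = None,
    settings: CoxSettings = CoxSettings(),
) -> CoxFit:
    """Fit a Cox proportional hazards model by Newton maximization of
    the log partial likelihood.

    Parameters
    ----------
    X : (n, p) array-like or DataFrame
        Covariate design.  Constant or exactly collinear columns raise
        with the offending names.
    time, event : (n,) arrays
        Follow-up time (> 0) and event indicator in {0, 1}.
    ties : {"efron", "breslow"}
        Tied-event-time correction.

    A separated or otherwise non-converging fit returns a
    ``CoxFit(converged=False)`` rather than raising.
    """
    if hasattr(X, "columns"):
        names = tuple(map(str, X.columns))
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(time)) != 1:
        X = X.T
    time = np.asarray(time, float)
    event = np.asarray(event)
    event = (event != 0).astype(np.int8)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    _validate_design(X, names, settings.collinearity_rtol)

    center = X.mean(axis=0)
    Xc = X - center
    order = np.argsort(time, kind="stable")
    Xs, es, ts = Xc[order], event[order], time[order]
    _, start = np.unique(ts, return_index=True)

    beta = np.zeros(p)
    loglik, grad, hess = _cox_quantities(Xs, es, start, beta, ties)
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        if np.max(np.abs(grad)) < settings.tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"singular information matrix during fit; columns {list(names)}"
            ) from None
        new_beta = beta + step
        new = _cox_quantities(Xs, es, start, new_beta, ties)
        # accept tiny fp-noise decreases near the optimum, halve real ones
        floor = loglik - 1e-9 * (abs(loglik) + 1.0)
        halved = 0
        while (not np.isfinite(new[0]) or new[0] < floor) and halved < settings.max_halvings:
            step = step / 2.0
            new_beta = beta + step
            new = _cox_quantities(Xs, es, start, new_beta, ties)
            halved += 1
        if not np.isfinite(new[0]) or new[0] < floor:
            break  # no ascent direction usable: report non-convergence
        beta, (loglik, grad, hess) = new_beta, new
    else:
        it = settings.max_iter
    if not converged and np.max(np.abs(grad)) < settings.tol:
        converged = True
    # monotone-likelihood (separation) guard: a diverging standardized
    # coefficient means the score vanished in the tail, not at an MLE
    if converged and np.max(np.abs(beta) * Xs.std(axis=0)) > 10.0:
        converged = False

    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"singular information matrix at optimum; columns {list(names)}"
        ) from None
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        log_partial_likelihood=loglik,
        n_iterations=it,
        converged=converged,
        ties_method=ties,
        names=tuple(names),
        n=n,
        n_events=int(event.sum()),
        _center=center,
    )


def predict_risk(fit: CoxFit, X, names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-subject linear predictor (log relative hazard).

    No baseline hazard is involved: the score orders subjects by risk,
    which is all concordance needs.  Covariates are centered with the
    training means, so scores are comparable across calls with the same
    fit.
    """
    if hasattr(X, "columns"):
        names = tuple(map(str, X.columns))
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    if names is not None and tuple(names) != fit.names:
        raise ValueError(f"design columns {tuple(names)} do not match fit {fit.names}")
    if X.shape[1] != len(fit.coefficients):
        raise ValueError(
            f"design has {X.shape[1]} columns, fit expects {len(fit.coefficients)}"
        )
    return (X - fit._center) @ fit.coefficients


# ---------------------------------------------------------------------------
# Harrell's concordance
# ---------------------------------------------------------------------------


def harrell_c(scores, time, event) -> ConcordanceResult:
    """Harrell's concordance index for right-censored data.

    Orientation: a *higher* score means higher predicted risk, i.e.
    shorter expected survival.  A pair is comparable iff the smaller
    observed time belongs to an event; it is concordant iff that subject
    has the strictly higher score, and score ties count 0.5.  Pairs with
    tied event times where both died are not comparable; at an identical
    time the event subject is treated as failing before the censored
    one.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = (np.asarray(event) != 0)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite risk scores")
    n = len(scores)
    # ordered-pair masks: row subject fails first
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None]
    e_j = event[None, :]
    first = (e_i & (t_i < t_j)) | (e_i & ~e_j & (t_i == t_j))
    np.fill_diagonal(first, False)
    s_i = scores[:, None]
    s_j = scores[None, :]
    concordant = int(np.sum(first & (s_i > s_j)))
    tied = int(np.sum(first & (s_i == s_j)))
    comparable = int(first.sum())
    if comparable == 0:
        raise ValueError("concordance undefined: no comparable pairs (all censored?)")
    c = (concordant + 0.5 * tied) / comparable
    return ConcordanceResult(
        c_index=c, comparable_pairs=comparable, concordant=concordant, tied_score=tied
    )


# ---------------------------------------------------------------------------
# Restricted cubic splines (Harrell form)
# ---------------------------------------------------------------------------


def default_knots(x, quantiles=(0.05, 0.35, 0.65, 0.95)) -> tuple[float, ...]:
    """Conventional knot placement at outer/inner quantiles of the data."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    k = tuple(float(q) for q in np.quantile(x, quantiles))
    if len(set(k)) != len(k):
        raise ValueError(f"degenerate data: duplicate quantile knots {k}")
    return k


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Restricted ("natural") cubic spline basis in Harrell's truncated
    power form: one linear column plus k−2 nonlinear columns, linear
    beyond the boundary knots.

    For knots t1 < … < tk and j = 1..k−2::

        f_j(x) = [ (x−tj)+^3 − (x−t_{k−1})+^3 (tk−tj)/(tk−t_{k−1})
                               + (x−tk)+^3 (t_{k−1}−tj)/(tk−t_{k−1}) ] / (tk−t1)^2

    The nonlinear columns vanish identically at and below the first
    knot.
    """
    x = np.asarray(x, float)
    t = np.asarray(spec.knots, float)
    k = len(t)
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or unordered knots")
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = t[j]
        term = (
            cube(x - tj)
            - cube(x - t[-2]) * (t[-1] - tj) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - tj) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostic
# ---------------------------------------------------------------------------


def kaplan_meier(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (event_times, S(t)) at
    the distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event) != 0
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, start = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), start)
    at_risk = len(t) - start
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
    surv = np.cumprod(factors)
    keep = d > 0
    return uniq[keep], surv[keep]


def ph_diagnostic(fit: CoxFit, X, time, event, transform: str = "km") -> dict:
    """Grambsch–Therneau test of the proportional-hazards assumption.

    Schoenfeld residuals at the event times are tested for association
    with a transform of time (default: the Kaplan–Meier scale,
    g(t) = 1 − KM(t−), which is robust to outlying follow-up times;
    ``"identity"`` and ``"rank"`` are also available).  Returns
    per-covariate chi-square statistics and p-values (df = 1) plus a
    global test (df = p).
    """
    if hasattr(X, "columns"):
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    time = np.asarray(time, float)
    if X.shape[0] == 1 and len(time) != 1:
        X = X.T
    event = (np.asarray(event) != 0)
    d = int(event.sum())
    if d == 0:
        raise ValueError("no events: PH diagnostic undefined")
    if d < 2:
        raise ValueError("PH diagnostic declined: fewer than 2 events")
    if not fit.converged:
        raise ValueError("PH diagnostic requires a converged fit")

    Xc = X - fit._center
    order = np.argsort(time, kind="stable")
    Xs, es, ts = Xc[order], event[order], time[order]
    _, start = np.unique(ts, return_index=True)

    eta = Xs @ fit.coefficients
    eta -= eta.max()
    w = np.exp(eta)
    wX = w[:, None] * Xs
    S0s = np.cumsum(w[::-1])[::-1]
    S1s = np.cumsum(wX[::-1], axis=0)[::-1]
    block = np.searchsorted(ts[start], ts)  # block id per subject
    xbar = S1s[start] / S0s[start][:, None]  # risk-set mean per block
    ev = np.flatnonzero(es)
    resid = Xs[ev] - xbar[block[ev]]  # Schoenfeld residuals, (d, p)
    ev_times = ts[ev]

    if transform == "km":
        kt, ks = kaplan_meier(time, event)
        # left-continuous KM at each event time
        pos = np.searchsorted(kt, ev_times, side="left") - 1
        km_minus = np.where(pos >= 0, ks[np.maximum(pos, 0)], 1.0)
        g = 1.0 - km_minus
    elif transform == "identity":
        g = ev_times.copy()
    elif transform == "rank":
        g = stats.rankdata(ev_times)
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    g = g - g.mean()
    gss = float(np.sum(g**2))
    if gss <= 0:
        raise ValueError("degenerate time transform (all event times tied)")

    V = fit.covariance
    u = resid.T @ g  # (p,)
    Vu = V @ u
    per_chi2 = d * Vu**2 / (np.diag(V) * gss)
    per_p = stats.chi2.sf(per_chi2, df=1)
    global_chi2 = float(d * (u @ Vu) / gss)
    global_p = float(stats.chi2.sf(global_chi2, df=len(u)))
    return {
        "per_covariate": {
            name: {"chi2": float(c), "p": float(p)}
            for name, c, p in zip(fit.names, per_chi2, per_p)
        },
        "global": {"chi2": global_chi2, "p": global_p, "df": len(u)},
        "transform": transform,
    }
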