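"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities from first
principles (literal pair enumeration, definitional partial-likelihood
sums) so the kernel implementations are checked against something that
shares no code path with them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pacsurv.synthetic import EffectSpec, GeneratorConfig, generate_cohort, make_redundancy_scenario


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def naive_concordance(scores, time, event):
    """Literal O(n^2) pair enumeration of Harrell's C.

    Comparable: the smaller observed time belongs to an event; tied
    times with both events are not comparable; at a tied time an event
    precedes a censored observation.  Score ties count 0.5.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n = len(scores)
    comparable = concordant = tied = 0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] < time[j]:
                first, second = i, j
            elif time[j] < time[i]:
                first, second = j, i
            else:  # tied observed times
                if event[i] and event[j]:
                    continue
                if event[i] and not event[j]:
                    first, second = i, j
                elif event[j] and not event[i]:
                    first, second = j, i
                else:
                    continue
            if not event[first]:
                continue
            comparable += 1
            if scores[first] > scores[second]:
                concordant += 1
            elif scores[first] == scores[second]:
                tied += 1
    if comparable == 0:
        return None
    return (concordant + 0.5 * tied) / comparable, comparable, concordant, tied


def naive_cox_loglik(betas, x, time, event, ties="efron"):
    """Definitional log partial likelihood for a single covariate,
    evaluated at an array of beta values.

    Events are grouped by tied time; the Efron correction downweights
    the tied events' own hazard contributions within the denominator,
    Breslow leaves the denominator whole.
    """
    betas = np.atleast_1d(np.asarray(betas, float))
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    ll = np.zeros_like(betas)
    for t in np.unique(time[event]):
        D = np.flatnonzero(event & (time == t))
        R = np.flatnonzero(time >= t)
        d = len(D)
        ll += betas * x[D].sum()
        exp_R = np.exp(np.outer(betas, x[R])).sum(axis=1)
        exp_D = np.exp(np.outer(betas, x[D])).sum(axis=1)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(exp_R - frac * exp_D)
    return ll


# ---------------------------------------------------------------------------
# Cohort fixtures (generated at session scope; everything is seeded)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def redundancy_cohort() -> pd.DataFrame:
    """Mid-size cohort where hazard depends on age and mPAP only and
    PAC is RC-coupled but conditionally null."""
    return make_redundancy_scenario(GeneratorConfig(n=6000, seed=11))


@pytest.fixture(scope="session")
def pac_effect_cohort() -> pd.DataFrame:
    """Cohort with a true HR of 1.5 on the indicator PAC < 3 mL/mmHg
    and no other hazard effects."""
    cfg = GeneratorConfig(
        n=5000,
        seed=21,
        coefficients=(EffectSpec("pac", float(np.log(1.5)), "below_threshold", 3.0),),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Cohort whose hazard is independent of every covariate."""
    return generate_cohort(GeneratorConfig(n=4000, seed=31, coefficients=()))


def random_survival_data(rng, n, censor_frac=0.3, tie_times=False, tie_scores=False):
    """Small random right-censored dataset for oracle comparisons."""
    if tie_times:
        time = rng.integers(1, max(3, n // 2), n).astype(float)
    else:
        time = rng.exponential(1.0, n)
    event = (rng.random(n) > censor_frac).astype(int)
    if tie_scores:
        scores = rng.integers(0, max(2, n // 3), n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, time, event
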