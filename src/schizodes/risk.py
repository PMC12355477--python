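"""Time-to-event generators for cardio-metabolic events and death.

First CHD, stroke and diabetes times come from published multivariable risk
equations (Framingham-type scores) evaluated on each patient's current
covariates.  A score gives the event probability over its published horizon
(10 years for CHD/stroke, 8 for diabetes in the shipped config); that
horizon risk is converted to a constant hazard and an exponential time is
drawn.  Hazards are piecewise-constant: whenever an event changes the
covariates (treatment start/stop, diabetes onset) the caller rescores and
redraws the affected clocks, which is distribution-preserving because the
exponential is memoryless.

Background mortality is an inverse-transform sample from the survival curve
implied by a national life table, with each annual death probability
adjusted for the schizophrenia standardised mortality ratio as
q' = 1 - (1 - q)^SMR.  Acute events (agranulocytosis, CHD, stroke) carry an
additional probability of death at occurrence.
"""

from __future__ import annotations

import math

import numpy as np

from .params import EpidemiologyParams, LifeTable, RiskCoefficients, RiskEquation
from .population import PatientProfile


def _linear_predictor(eq: RiskEquation, profile: PatientProfile) -> float:
    lp = 0.0
    for term in eq.terms:
        try:
            x = profile.covariate(term.covariate)
        except KeyError:
            raise KeyError(
                f"risk equation {eq.variant or eq.form!r} requires covariate "
                f"{term.covariate!r} missing from the patient profile"
            ) from None
        if term.transform == "log":
            if x <= 0:
                raise ValueError(
                    f"covariate {term.covariate!r} = {x} not positive under log transform"
                )
            x = math.log(x)
        lp += term.coef * x
    return lp


def score_risk(outcome: str, profile: PatientProfile, coeffs: RiskCoefficients) -> float:
    """Event probability over the score's published horizon, in (0, 1).

    ``outcome`` is one of "chd", "stroke", "diabetes".  The caller is
    responsible for not scoring an outcome the patient already has.
    """
    eq = coeffs.equation(outcome)
    lp = _linear_predictor(eq, profile)
    if eq.form == "logistic":
        risk = 1.0 / (1.0 + math.exp(-(eq.intercept + lp)))
    else:  # cox baseline-survival form
        risk = 1.0 - eq.baseline_survival ** math.exp(lp - eq.mean_lp)
    # keep strictly inside (0, 1) so the hazard conversion stays defined
    return min(max(risk, 1e-15), 1.0 - 1e-15)


def risk_to_rate(risk: float, horizon: float) -> float:
    """Constant hazard reproducing ``risk`` over ``horizon`` years."""
    if not (0.0 <= risk < 1.0):
        raise ValueError(f"risk must be in [0, 1), got {risk}")
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return -math.log1p(-risk) / horizon


def risk_to_time(risk: float, horizon: float, rng: np.random.Generator) -> float:
    """Exponential event time for a horizon risk; ``risk`` 0 never fires."""
    rate = risk_to_rate(risk, horizon)
    if rate == 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def sample_exponential(rate: float, rng: np.random.Generator) -> float:
    """Exponential sample at the given rate; rate 0 means never."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if rate == 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def adjusted_annual_q(lt: LifeTable, sex: str, smr: float) -> np.ndarray:
    """Life-table annual death probabilities adjusted for excess mortality."""
    q = lt.annual_q(sex)
    return 1.0 - (1.0 - q) ** smr


def sample_time_to_death(
    age: float,
    sex: str,
    lt: LifeTable,
    smr: float,
    rng: np.random.Generator,
) -> float:
    """Inverse-transform draw from the life-table survival curve.

    Survival compounds SMR-adjusted annual death probabilities starting at
    the table year of the patient's (floored) current age; within the year
    of death the time is uniform.  Death is certain by ``max_age`` (the
    final table row has q = 1), so the returned time never exceeds
    ``max_age - age``.
    """
    if smr <= 0:
        raise ValueError(f"smr must be positive, got {smr}")
    a0 = int(math.floor(age))
    first = lt.ages[0]
    if a0 < first or a0 > lt.max_age:
        raise ValueError(f"age {age} outside life table support [{first}, {lt.max_age}]")
    q = adjusted_annual_q(lt, sex, smr)[a0 - first:]
    u = rng.random()
    surv = 1.0
    for k, qk in enumerate(q):
        surv_next = surv * (1.0 - qk)
        if u > surv_next:
            frac = (surv - u) / (surv - surv_next)  # uniform within the year
            return min(float(k) + frac, lt.max_age - age)
        surv = surv_next
    return float(lt.max_age - age)  # unreachable: final q is 1


def acute_fatality(event: str, epi: EpidemiologyParams, rng: np.random.Generator) -> bool:
    """Bernoulli death-at-occurrence draw for an acute event."""
    try:
        p = epi.case_fatality[event]
    except KeyError:
        raise KeyError(f"no case-fatality probability configured for event {event!r}") from None
    return bool(rng.random() < p)
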