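"""Convert trajectories into discounted and undiscounted QALYs and costs.

Quality-adjusted time and running costs are accrued as exact integrals over
the piecewise-constant state between events, with continuous discounting

    w(t0, t1) = integral_{t0}^{t1} (1+r)^{-t} dt
              = ((1+r)^{-t0} - (1+r)^{-t1}) / ln(1+r)

(r = 0 reduces to the plain duration).  Lump costs (relapse episodes, acute
event management, death) are charged at the event time's discount factor.

Utilities combine additively with a floor at zero: the utility in an
interval is max(0, state utility - sum of active decrements).  QALY losses
are decomposed into a cardio-metabolic bucket (post-CHD, post-stroke,
diabetes) and an "other side-effects" bucket (EPS, weight gain, sedation,
sexual dysfunction, tardive dyskinesia, agranulocytosis); when the floor
binds, the realised loss is split between the buckets in proportion to
their unfloored contributions so the decomposition sums exactly to total
QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .params import CostParams, ParameterSet, UtilityParams
from .engine import Trajectory

CM_CONDITIONS = frozenset({"post_chd", "post_stroke", "diabetes"})
OTHER_SE_CONDITIONS = frozenset(
    {"eps", "sedation", "sexual_dysfunction", "weight_gain", "tardive_dyskinesia",
     "agranulocytosis"}
)

COST_COMPONENTS = ("drug", "stable_care", "relapse", "se_management", "cardiometabolic", "death")


class OutcomeError(ValueError):
    pass


def discount_factor(r: float, t: float) -> float:
    """Present-value factor (1+r)^(-t)."""
    return (1.0 + r) ** (-t)


def discount_weight(r: float, t0: float, t1: float) -> float:
    """Discounted duration of the interval [t0, t1] in years."""
    if t1 < t0:
        raise OutcomeError(f"t1 ({t1}) < t0 ({t0})")
    if r < 0:
        raise OutcomeError(f"negative discount rate {r}")
    if r == 0.0:
        return t1 - t0
    ln = math.log1p(r)
    return ((1.0 + r) ** (-t0) - (1.0 + r) ** (-t1)) / ln


@dataclass
class TrajectorySummary:
    """Outcome decomposition of one trajectory.

    QALY loss buckets are reported as negative numbers; undiscounted unless
    the field name says otherwise.  Cost components are discounted GBP.
    """

    years_stable: float = 0.0
    qalys_excl_se: float = 0.0
    qaly_loss_cardiometabolic: float = 0.0
    qaly_loss_other_se: float = 0.0
    qalys_undiscounted: float = 0.0
    qalys_excl_se_discounted: float = 0.0
    qaly_loss_cardiometabolic_discounted: float = 0.0
    qaly_loss_other_se_discounted: float = 0.0
    qalys_discounted: float = 0.0
    cost_components: Dict[str, float] = dc_field(
        default_factory=lambda: {k: 0.0 for k in COST_COMPONENTS}
    )
    total_cost_discounted: float = 0.0
    total_cost_undiscounted: float = 0.0

    def to_dict(self) -> Dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in (
                "years_stable",
                "qalys_excl_se",
                "qaly_loss_cardiometabolic",
                "qaly_loss_other_se",
                "qalys_undiscounted",
                "qalys_discounted",
                "total_cost_discounted",
                "total_cost_undiscounted",
            )
        }
        for k in COST_COMPONENTS:
            d[f"cost_{k}"] = self.cost_components[k]
        return d


@dataclass
class _ReplayState:
    """Minimal state mirror used when replaying a recorded trajectory."""

    disease_state: str = "stable"
    on_treatment: bool = False
    drug_cost_rate: float = 0.0
    active_conditions: set = dc_field(default_factory=set)
    se_expiry_times: Dict[str, float] = dc_field(default_factory=dict)


def accrue_interval(
    state,
    t0: float,
    t1: float,
    u: UtilityParams,
    c: CostParams,
    r: float,
    acc: TrajectorySummary,
) -> None:
    """Accrue utilities and running costs for a constant-state interval.

    ``state`` needs ``disease_state``, ``on_treatment``, ``drug_cost_rate``
    and ``active_conditions``; the engine guarantees the state only changes
    at interval endpoints.
    """
    if t1 <= t0:
        return
    dt = t1 - t0
    dw = discount_weight(r, t0, t1)
    su = u.u_stable if state.disease_state == "stable" else u.u_relapse

    dec = u.decrement_per_condition
    loss_cm = sum(dec.get(k, 0.0) for k in state.active_conditions if k in CM_CONDITIONS)
    loss_oth = sum(dec.get(k, 0.0) for k in state.active_conditions if k in OTHER_SE_CONDITIONS)
    gross_loss = loss_cm + loss_oth
    utility = max(0.0, su - gross_loss)
    realised_loss = su - utility  # <= gross_loss when the floor binds
    scale = realised_loss / gross_loss if gross_loss > 0 else 0.0

    if state.disease_state == "stable":
        acc.years_stable += dt
    acc.qalys_excl_se += su * dt
    acc.qaly_loss_cardiometabolic -= loss_cm * scale * dt
    acc.qaly_loss_other_se -= loss_oth * scale * dt
    acc.qalys_undiscounted += utility * dt
    acc.qalys_excl_se_discounted += su * dw
    acc.qaly_loss_cardiometabolic_discounted -= loss_cm * scale * dw
    acc.qaly_loss_other_se_discounted -= loss_oth * scale * dw
    acc.qalys_discounted += utility * dw

    comp = acc.cost_components
    undisc = 0.0
    if state.on_treatment:
        comp["drug"] += state.drug_cost_rate * dw
        undisc += state.drug_cost_rate * dt
    comp["stable_care"] += c.annual_stable_care_cost * dw
    undisc += c.annual_stable_care_cost * dt
    if state.disease_state == "relapse" and c.relapse_cost_dialect == "per_year":
        comp["relapse"] += c.relapse_episode_cost * dw
        undisc += c.relapse_episode_cost * dt
    chronic = c.annual_chronic_cost
    for cond in state.active_conditions:
        rate = chronic.get(cond, 0.0)
        if rate:
            bucket = "cardiometabolic" if cond in CM_CONDITIONS else "se_management"
            comp[bucket] += rate * dw
            undisc += rate * dt
    acc.total_cost_undiscounted += undisc


def apply_event_outcomes(
    event_type: str,
    payload: dict,
    t: float,
    c: CostParams,
    u: UtilityParams,
    r: float,
    acc: TrajectorySummary,
) -> None:
    """Charge the lump costs attached to a realised event."""
    df = discount_factor(r, t)
    comp = acc.cost_components

    def lump(bucket: str, amount: float) -> None:
        comp[bucket] += amount * df
        acc.total_cost_undiscounted += amount

    if event_type == "relapse":
        if c.relapse_cost_dialect == "per_episode":
            lump("relapse", c.relapse_episode_cost)
    elif event_type in ("chd", "stroke"):
        lump("cardiometabolic", c.per_event_acute_cost.get(event_type, 0.0))
    elif event_type == "treatment_start":
        for se in payload.get("side_effects", ()):
            lump("se_management", c.per_event_acute_cost.get(se, 0.0))
    elif event_type == "death":
        lump("death", c.death_cost)
    elif event_type in ("remission", "discontinuation", "tardive_dyskinesia",
                        "diabetes", "horizon_end"):
        pass
    else:
        raise OutcomeError(f"unknown event type {event_type!r}")


def summarise_trajectory(traj: Trajectory, pset: ParameterSet) -> TrajectorySummary:
    """Replay a recorded trajectory into its outcome decomposition.

    Deterministic: every stochastic outcome (side-effect draws, switch
    decisions, fatality flags) is recorded in the event payloads, so the
    replay needs no random numbers.
    """
    u, c, r = pset.utilities, pset.costs, pset.sim.annual_discount_rate
    acc = TrajectorySummary()
    st = _ReplayState()
    t_prev = 0.0
    for ev in traj.events:
        # split the interval at short-term side-effect expiries inside it
        while True:
            expiring = [
                (te, cond) for cond, te in st.se_expiry_times.items() if t_prev < te < ev.time
            ]
            if not expiring:
                break
            te, cond = min(expiring)
            accrue_interval(st, t_prev, te, u, c, r, acc)
            st.active_conditions.discard(cond)
            del st.se_expiry_times[cond]
            t_prev = te
        accrue_interval(st, t_prev, ev.time, u, c, r, acc)
        # expiries landing exactly on the event boundary
        for cond, te in list(st.se_expiry_times.items()):
            if te <= ev.time:
                st.active_conditions.discard(cond)
                del st.se_expiry_times[cond]
        t_prev = ev.time

        apply_event_outcomes(ev.type, ev.payload, ev.time, c, u, r, acc)
        et = ev.type
        if et == "treatment_start":
            st.on_treatment = True
            st.drug_cost_rate = pset.treatment(ev.payload["treatment"]).annual_drug_cost
            if not ev.payload.get("restart", False):
                for se in ev.payload.get("side_effects", ()):
                    st.active_conditions.add(se)
                    st.se_expiry_times[se] = ev.time + u.short_term_se_duration
        elif et == "relapse":
            st.disease_state = "relapse"
            if ev.payload.get("switch", False):
                st.on_treatment = False  # the paired treatment_start follows
        elif et == "remission":
            st.disease_state = "stable"
        elif et == "discontinuation":
            st.on_treatment = False
        elif et == "tardive_dyskinesia":
            st.active_conditions.add("tardive_dyskinesia")
        elif et == "diabetes":
            st.active_conditions.add("diabetes")
        elif et == "chd":
            if not ev.payload.get("fatal", False):
                st.active_conditions.add("post_chd")
        elif et == "stroke":
            if not ev.payload.get("fatal", False):
                st.active_conditions.add("post_stroke")
        # death / horizon_end: terminal, loop ends with them
    acc.total_cost_discounted = sum(acc.cost_components.values())
    return acc


def summarise_cohort(
    trajs: List[Trajectory], pset: ParameterSet
) -> pd.DataFrame:
    """Per-trajectory summaries as a data frame (one row per trajectory)."""
    rows = []
    for tr in trajs:
        d = summarise_trajectory(tr, pset).to_dict()
        d["patient_id"] = tr.patient_id
        d["replication"] = tr.replication
        d["sequence"] = tr.sequence.label()
        d["first_line"] = tr.sequence.first_line
        rows.append(d)
    return pd.DataFrame(rows)
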