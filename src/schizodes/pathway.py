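"""Treatment-line logic and schizophrenia-specific event-time generators.

Patients enter stable on a first-line antipsychotic.  Relapse times are
exponential with the untreated annual probability converted to a hazard and
multiplied by a treatment/adherence modifier; remission follows each
relapse deterministically after the configured episode length.  On relapse
patients switch to the next treatment line with a configured probability;
after two consecutive failures the next switch is to clozapine, the fixed
third and final line.  All-cause discontinuation and tardive dyskinesia are
exponential with treatment-specific annual probabilities; discontinuation
removes the metabolic shifts and drug cost and raises the relapse hazard to
its untreated level.  Switching on grounds of side-effects alone is
deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Set

import numpy as np

from .params import (
    EpidemiologyParams,
    ParameterSet,
    SimulationConfig,
    TreatmentProfile,
    UtilityParams,
    METABOLIC_MARKERS,
)
from .population import PatientProfile


class ContractError(RuntimeError):
    """An operation was invoked outside its stated precondition."""


@dataclass
class TreatmentSequence:
    """First line, optional second line, clozapine as the fixed last line.

    ``second_line=None`` models the second-line scenario where the next
    switch goes straight to clozapine.
    """

    first_line: str
    second_line: Optional[str]

    def __post_init__(self) -> None:
        if self.second_line is not None and self.first_line == self.second_line:
            raise ValueError("first and second line must differ")

    def label(self) -> str:
        return f"{self.first_line}->{self.second_line or 'clozapine'}"


@dataclass
class PatientState:
    """Time-varying record of one simulated patient."""

    profile: PatientProfile
    baseline_metabolics: Dict[str, float]
    disease_state: str = "stable"  # "stable" | "relapse"
    treatment: Optional[TreatmentProfile] = None
    line_index: int = 1
    consecutive_failures: int = 0
    on_treatment: bool = False
    #: permanent conditions plus currently active short-term side-effects
    active_conditions: Set[str] = field(default_factory=set)
    #: absolute expiry time per active short-term side-effect
    se_expiry_times: Dict[str, float] = field(default_factory=dict)
    alive: bool = True
    tried_treatments: Set[str] = field(default_factory=set)

    @classmethod
    def from_profile(cls, profile: PatientProfile) -> "PatientState":
        base = {m: float(getattr(profile, m)) for m in METABOLIC_MARKERS}
        state = cls(profile=profile, baseline_metabolics=base)
        if profile.prior_chd:
            state.active_conditions.add("post_chd")
        if profile.prior_stroke:
            state.active_conditions.add("post_stroke")
        if profile.diabetes:
            state.active_conditions.add("diabetes")
        return state

    def _sync_metabolics(self) -> None:
        """Current marker values = baseline + active treatment shifts.

        Recomputing from baseline (rather than adding/subtracting) makes the
        shifts disappear exactly on discontinuation.
        """
        deltas = self.treatment.metabolic_deltas if (self.on_treatment and self.treatment) else {}
        for m in METABOLIC_MARKERS:
            setattr(self.profile, m, self.baseline_metabolics[m] + deltas.get(m, 0.0))


def relapse_hazard_modifier(state: PatientState, epi: EpidemiologyParams) -> float:
    """Multiplier on the untreated relapse hazard.

    Off treatment: 1.  On treatment: the risk ratio interpolated towards 1
    by the adherence weight (LAI routes force full adherence, weight 0).
    """
    if not state.on_treatment or state.treatment is None:
        return 1.0
    rr = state.treatment.relapse_risk_ratio
    if state.treatment.route == "lai":
        w = 0.0
    else:
        w = epi.adherence_relapse_weights[state.profile.adherence_level]
    return rr + w * (1.0 - rr)


def untreated_relapse_rate(epi: EpidemiologyParams) -> float:
    return -math.log1p(-epi.annual_relapse_prob_no_treatment)


def sample_time_to_relapse(
    state: PatientState, epi: EpidemiologyParams, rng: np.random.Generator
) -> float:
    """Exponential time (years from now) to the next relapse."""
    if state.disease_state != "stable":
        raise ContractError("relapse clock only runs in the stable state")
    rate = untreated_relapse_rate(epi) * relapse_hazard_modifier(state, epi)
    if rate <= 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def schedule_remission(relapse_time: float, epi: EpidemiologyParams) -> float:
    """Absolute remission time: fixed episode length after the relapse."""
    return relapse_time + epi.remission_duration


def sample_time_to_discontinuation(tx: TreatmentProfile, rng: np.random.Generator) -> float:
    rate = -math.log1p(-tx.annual_discontinuation_prob) if tx.annual_discontinuation_prob < 1 else math.inf
    if rate == 0.0:
        return math.inf
    if math.isinf(rate):
        return 0.0
    return rng.exponential(1.0 / rate)


def sample_time_to_td(tx: TreatmentProfile, rng: np.random.Generator) -> float:
    rate = -math.log1p(-tx.annual_td_prob) if tx.annual_td_prob < 1 else math.inf
    if rate == 0.0:
        return math.inf
    if math.isinf(rate):
        return 0.0
    return rng.exponential(1.0 / rate)


def apply_treatment_start(
    state: PatientState,
    tx: TreatmentProfile,
    t: float,
    utilities: UtilityParams,
    epi: EpidemiologyParams,
    rng: np.random.Generator,
) -> dict:
    """Start (or restart) a treatment at absolute time ``t``.

    Applies the metabolic shifts, draws each short-term side-effect
    (Bernoulli on its 3-month incidence, active for the configured
    duration), and for clozapine performs the agranulocytosis case-fatality
    check.  Returns the ``treatment_start`` event payload; the caller is
    responsible for rescheduling every clock whose hazard changed.
    """
    if not state.alive:
        raise ContractError("cannot start treatment on a dead patient")
    if state.on_treatment:
        raise ContractError("cannot start a treatment while another is active")
    restart = state.treatment is not None and state.treatment.name == tx.name
    if not restart and not tx.is_clozapine and tx.name in state.tried_treatments:
        raise ContractError(f"treatment {tx.name!r} already tried")

    state.treatment = tx
    state.on_treatment = True
    state.tried_treatments.add(tx.name)
    state._sync_metabolics()

    side_effects = []
    fatal_agranulocytosis = False
    if not restart:  # short-term tolerability burden is charged once per drug
        for se, p in tx.short_term_se_probs.items():
            if p > 0.0 and rng.random() < p:
                side_effects.append(se)
                state.active_conditions.add(se)
                state.se_expiry_times[se] = t + utilities.short_term_se_duration
                if se == "agranulocytosis":
                    from .risk import acute_fatality

                    fatal_agranulocytosis = acute_fatality("agranulocytosis", epi, rng)
    return {
        "treatment": tx.name,
        "line": state.line_index,
        "restart": restart,
        "side_effects": side_effects,
        "fatal_agranulocytosis": fatal_agranulocytosis,
    }


def apply_treatment_stop(state: PatientState) -> None:
    """Stop the active treatment: metabolic shifts disappear, drug cost and
    the discontinuation/tardive-dyskinesia clocks stop accruing."""
    state.on_treatment = False
    state._sync_metabolics()


def next_line_treatment(
    state: PatientState, seq: TreatmentSequence, pset: ParameterSet
) -> TreatmentProfile:
    """The treatment a switching patient moves to, honouring the
    two-consecutive-failures clozapine rule and the fixed last line."""
    if state.consecutive_failures >= 2 or seq.second_line is None or state.line_index >= 2:
        return pset.clozapine
    return pset.treatment(seq.second_line)


def resolve_relapse(
    state: PatientState,
    seq: TreatmentSequence,
    pset: ParameterSet,
    t: float,
    rng: np.random.Generator,
) -> dict:
    """Handle a relapse event at absolute time ``t``.

    Enters the relapse state, increments the consecutive-failure counter,
    and with the configured probability switches line (stopping the current
    treatment; the caller starts the new one).  Patients already on
    clozapine never switch further.  Returns a payload describing the
    decision; remission is scheduled by the caller at
    ``t + remission_duration``.
    """
    if state.disease_state == "relapse":
        raise ContractError("relapse during an ongoing relapse episode")
    epi = pset.epidemiology
    sim = pset.sim
    state.disease_state = "relapse"

    on_clozapine = state.treatment is not None and state.treatment.is_clozapine
    switch = (not on_clozapine) and (rng.random() < epi.switch_prob_after_relapse)

    counts_failure = switch or sim.nonswitch_relapse_counts_as_failure
    if counts_failure:
        state.consecutive_failures += 1

    payload: dict = {"switch": switch, "failures": state.consecutive_failures}
    if switch:
        new_tx = next_line_treatment(state, seq, pset)
        payload["switch_to"] = new_tx.name
        payload["new_line"] = 3 if new_tx.is_clozapine else state.line_index + 1
    return payload
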