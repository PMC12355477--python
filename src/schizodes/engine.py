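"""The discrete event simulation core.

For each patient a list of pending event times is maintained; the loop
repeatedly (a) selects the earliest pending event, (b) updates the patient
state, and (c) regenerates only the clocks whose hazards the event changed
(exponential clocks are memoryless, so retained clocks keep their scheduled
times with the correct distribution).  The loop ends at the time horizon or
at death.

Randomness is organised as named substreams keyed by
(master seed, patient, replication, clock): with common random numbers
(the default) the key excludes the treatment sequence, so the baseline
cohort, background death times and the initial uniforms of shared clocks
coincide across compared sequences until their pathways diverge; with the
flag off every sequence gets fully independent streams.
"""

from __future__ import annotations

import copy
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import pathway as pw
from . import risk as rk
from .params import ParameterSet, RISK_OUTCOMES
from .pathway import ContractError, PatientState, TreatmentSequence
from .population import PatientProfile, generate_cohort

EVENT_TYPES = (
    "treatment_start",
    "relapse",
    "remission",
    "discontinuation",
    "tardive_dyskinesia",
    "chd",
    "stroke",
    "diabetes",
    "death",
    "horizon_end",
)

ONCE_ONLY_EVENTS = ("tardive_dyskinesia", "chd", "stroke", "diabetes", "death", "horizon_end")

#: Substream index per clock; the cohort stream is keyed per patient only.
_CLOCK_IDS = {
    "death": 0,
    "relapse": 1,
    "discontinuation": 2,
    "tardive_dyskinesia": 3,
    "chd": 4,
    "stroke": 5,
    "diabetes": 6,
    "side_effects": 7,
    "switch": 8,
}


class EngineError(RuntimeError):
    """Internal simulation failure (e.g. runaway event loop)."""


@dataclass(slots=True)
class EventRecord:
    time: float
    type: str
    payload: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    patient_id: int
    replication: int
    sequence: TreatmentSequence
    events: List[EventRecord]
    final_state: PatientState


def clock_streams(
    master_seed: int,
    patient_id: int,
    replication: int,
    sequence_key: int = 0,
) -> Dict[str, np.random.Generator]:
    """Independent named RNG substreams for one patient-replication."""
    return {
        name: np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence((master_seed, patient_id, replication, cid, sequence_key))
            )
        )
        for name, cid in _CLOCK_IDS.items()
    }


def sequence_stream_key(seq: TreatmentSequence, crn: bool) -> int:
    """0 under common random numbers; a sequence-specific key otherwise."""
    if crn:
        return 0
    return zlib.crc32(seq.label().encode()) & 0x7FFFFFFF


def next_event(
    pending: Dict[str, float], priority: Optional[List[str]] = None
) -> Tuple[str, float]:
    """Earliest pending event; exact ties broken by the fixed priority order."""
    if not pending:
        raise ContractError("next_event called with no pending events")
    if priority is None:
        priority = ["death", "chd", "stroke", "diabetes", "relapse",
                    "remission", "discontinuation", "tardive_dyskinesia"]
    rank = {name: i for i, name in enumerate(priority)}
    best = min(pending.items(), key=lambda kv: (kv[1], rank.get(kv[0], len(rank))))
    return best[0], best[1]


class _Sim:
    """Single-trajectory simulation state and clock management."""

    def __init__(
        self,
        profile: PatientProfile,
        seq: TreatmentSequence,
        pset: ParameterSet,
        streams: Dict[str, np.random.Generator],
        start_line: int = 1,
        initial_failures: int = 0,
    ) -> None:
        self.pset = pset
        self.seq = seq
        self.streams = streams
        self.state = PatientState.from_profile(copy.copy(profile))
        self.state.line_index = start_line
        self.state.consecutive_failures = initial_failures
        self.t = 0.0
        self.pending: Dict[str, float] = {}
        self.events: List[EventRecord] = []
        self.horizon = pset.sim.horizon
        self._rank = {name: i for i, name in enumerate(pset.sim.tie_priority)}

    # -- clock scheduling ---------------------------------------------------

    def _schedule_death(self) -> None:
        t = rk.sample_time_to_death(
            self.state.profile.age,
            self.state.profile.sex,
            self.pset.life_table,
            self.pset.epidemiology.smr_schizophrenia,
            self.streams["death"],
        )
        self.pending["death"] = self.t + t

    def _reschedule_risk(self, outcomes=RISK_OUTCOMES) -> None:
        for oc in outcomes:
            if not self._eligible_first(oc):
                self.pending.pop(oc, None)
                continue
            eq = self.pset.risk_coefficients.equation(oc)
            risk = rk.score_risk(oc, self.state.profile, self.pset.risk_coefficients)
            dt = rk.risk_to_time(risk, eq.horizon_years, self.streams[oc])
            self.pending[oc] = self.t + dt

    def _eligible_first(self, outcome: str) -> bool:
        p = self.state.profile
        if outcome == "chd":
            return not p.prior_chd
        if outcome == "stroke":
            return not p.prior_stroke
        if outcome == "diabetes":
            return not p.diabetes
        return False

    def _reschedule_relapse(self) -> None:
        if self.state.disease_state != "stable":
            self.pending.pop("relapse", None)
            return
        dt = pw.sample_time_to_relapse(self.state, self.pset.epidemiology, self.streams["relapse"])
        self.pending["relapse"] = self.t + dt

    def _reschedule_treatment_clocks(self) -> None:
        tx = self.state.treatment
        if not self.state.on_treatment or tx is None:
            self.pending.pop("discontinuation", None)
            self.pending.pop("tardive_dyskinesia", None)
            return
        self.pending["discontinuation"] = self.t + pw.sample_time_to_discontinuation(
            tx, self.streams["discontinuation"]
        )
        if "tardive_dyskinesia" in self.state.active_conditions:
            self.pending.pop("tardive_dyskinesia", None)
        else:
            self.pending["tardive_dyskinesia"] = self.t + pw.sample_time_to_td(
                tx, self.streams["tardive_dyskinesia"]
            )

    # -- event handlers -----------------------------------------------------

    def _emit(self, etype: str, payload: Optional[dict] = None, t: Optional[float] = None) -> None:
        self.events.append(EventRecord(self.t if t is None else t, etype, payload or {}))

    def _die(self, cause: str) -> None:
        self._emit("death", {"cause": cause})
        self.state.alive = False

    def _start_treatment(self, tx) -> None:
        payload = pw.apply_treatment_start(
            self.state, tx, self.t, self.pset.utilities, self.pset.epidemiology,
            self.streams["side_effects"],
        )
        self._emit("treatment_start", payload)
        if payload["fatal_agranulocytosis"]:
            self._die("agranulocytosis")
            return
        self._reschedule_relapse()
        self._reschedule_treatment_clocks()
        self._reschedule_risk()

    def _on_relapse(self) -> None:
        payload = pw.resolve_relapse(self.state, self.seq, self.pset, self.t, self.streams["switch"])
        self._emit("relapse", payload)
        self.pending.pop("relapse", None)
        self.pending["remission"] = pw.schedule_remission(self.t, self.pset.epidemiology)
        if payload["switch"]:
            if self.state.on_treatment:
                pw.apply_treatment_stop(self.state)
            self.state.line_index = payload["new_line"]
            new_tx = self.pset.clozapine if payload["new_line"] == 3 else self.pset.treatment(payload["switch_to"])
            self._start_treatment(new_tx)

    def _on_remission(self) -> None:
        self.pending.pop("remission", None)
        self.state.disease_state = "stable"
        self._emit("remission")
        if (
            not self.state.on_treatment
            and self.pset.sim.restart_treatment_at_remission
            and self.state.treatment is not None
        ):
            self._start_treatment(self.state.treatment)
        else:
            self._reschedule_relapse()

    def _on_discontinuation(self) -> None:
        pw.apply_treatment_stop(self.state)
        self._emit("discontinuation", {"treatment": self.state.treatment.name})
        self.pending.pop("discontinuation", None)
        self.pending.pop("tardive_dyskinesia", None)
        self._reschedule_relapse()
        self._reschedule_risk()  # metabolic shifts disappeared

    def _on_td(self) -> None:
        self.pending.pop("tardive_dyskinesia", None)
        self.state.active_conditions.add("tardive_dyskinesia")
        self._emit("tardive_dyskinesia")

    def _on_cardiometabolic(self, oc: str) -> None:
        self.pending.pop(oc, None)
        p = self.state.profile
        if oc == "diabetes":
            p.diabetes = True
            self.state.active_conditions.add("diabetes")
            self._emit("diabetes")
            self._reschedule_risk(("chd", "stroke"))  # diabetes is a covariate
            return
        fatal = rk.acute_fatality(oc, self.pset.epidemiology, self.streams[oc])
        self._emit(oc, {"fatal": fatal})
        if fatal:
            self._die(oc)
            return
        if oc == "chd":
            p.prior_chd = True
            self.state.active_conditions.add("post_chd")
            self._reschedule_risk(("stroke",))
        else:
            p.prior_stroke = True
            self.state.active_conditions.add("post_stroke")

    # -- main loop ----------------------------------------------------------

    def run(self) -> Trajectory:
        self._schedule_death()
        first_tx = self.pset.treatment(self.seq.first_line)
        self._start_treatment(first_tx)
        guard = self.pset.sim.max_events_per_trajectory
        n = 0
        while self.state.alive:
            n += 1
            if n > guard:
                raise EngineError(
                    f"event guard exceeded ({guard} events) for patient "
                    f"{self.state.profile.id}, sequence {self.seq.label()}; "
                    f"pending={self.pending}"
                )
            etype, te = next_event(self.pending, self.pset.sim.tie_priority)
            if te >= self.horizon:
                self._emit("horizon_end", t=self.horizon)
                break
            self.t = te
            if etype == "death":
                self._die("background")
            elif etype == "relapse":
                self._on_relapse()
            elif etype == "remission":
                self._on_remission()
            elif etype == "discontinuation":
                self._on_discontinuation()
            elif etype == "tardive_dyskinesia":
                self._on_td()
            else:
                self._on_cardiometabolic(etype)
        return Trajectory(
            patient_id=self.state.profile.id,
            replication=0,
            sequence=self.seq,
            events=self.events,
            final_state=self.state,
        )


def simulate_patient(
    profile: PatientProfile,
    seq: TreatmentSequence,
    pset: ParameterSet,
    streams: Dict[str, np.random.Generator],
    start_line: int = 1,
    initial_failures: int = 0,
) -> Trajectory:
    """Simulate one patient under one treatment sequence."""
    return _Sim(profile, seq, pset, streams, start_line, initial_failures).run()


def run_cohort(
    pset: ParameterSet,
    seq: TreatmentSequence,
    cohort: Optional[List[PatientProfile]] = None,
    n_patients: Optional[int] = None,
    n_replications: Optional[int] = None,
    start_line: int = 1,
    initial_failures: int = 0,
) -> List[Trajectory]:
    """Simulate every patient-replication for one treatment sequence.

    The cohort, if not supplied, is generated from the baseline summary with
    a stream keyed by the master seed only, so every sequence sees the same
    patients.  Replication ``r`` of patient ``i`` uses substreams keyed by
    (master seed, i, r, clock) — shared across sequences under common random
    numbers.
    """
    sim = pset.sim
    n_pat = n_patients if n_patients is not None else sim.n_patients
    n_rep = n_replications if n_replications is not None else sim.n_replications
    if cohort is None:
        cohort = baseline_cohort(pset, n_pat)
    key = sequence_stream_key(seq, sim.common_random_numbers)
    out: List[Trajectory] = []
    for profile in cohort:
        for rep in range(n_rep):
            streams = clock_streams(sim.master_seed, profile.id, rep, key)
            traj = simulate_patient(profile, seq, pset, streams, start_line, initial_failures)
            traj.replication = rep
            out.append(traj)
    return out


#: entropy tag separating the cohort stream from all clock streams
_COHORT_STREAM_TAG = 987654321


def baseline_cohort(pset: ParameterSet, n: Optional[int] = None) -> List[PatientProfile]:
    """The shared entry cohort (stream keyed by master seed only)."""
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((pset.sim.master_seed, _COHORT_STREAM_TAG)))
    )
    return generate_cohort(pset.baseline, n if n is not None else pset.sim.n_patients, rng)


# ---------------------------------------------------------------------------
# Trajectory checks and export
# ---------------------------------------------------------------------------

def check_trajectory(traj: Trajectory, horizon: float) -> List[str]:
    """Structural invariant violations of one trajectory (empty = valid)."""
    issues: List[str] = []
    ev = traj.events
    if not ev or ev[0].type != "treatment_start" or ev[0].time != 0.0:
        issues.append("trajectory must start with treatment_start at t=0")
    if ev and ev[-1].type not in ("death", "horizon_end"):
        issues.append(f"terminal event is {ev[-1].type!r}")
    times = [e.time for e in ev]
    if any(b < a for a, b in zip(times, times[1:])):
        issues.append("event times decrease")
    from collections import Counter

    counts = Counter(e.type for e in ev)
    for etype in ONCE_ONLY_EVENTS:
        if counts.get(etype, 0) > 1:
            issues.append(f"once-only event {etype!r} occurred {counts[etype]} times")
    for i, e in enumerate(ev):
        if e.type in ("death", "horizon_end") and i != len(ev) - 1:
            issues.append(f"{e.type} not terminal")
        if e.time > horizon + 1e-12:
            issues.append(f"event {e.type} after horizon")
    return issues


def trajectories_to_frame(trajs: List[Trajectory]) -> pd.DataFrame:
    """Long-format event table (one row per event)."""
    rows = []
    for tr in trajs:
        for e in tr.events:
            rows.append(
                {
                    "patient_id": tr.patient_id,
                    "replication": tr.replication,
                    "sequence": tr.sequence.label(),
                    "time": e.time,
                    "event": e.type,
                    "payload": json.dumps(e.payload, sort_keys=True),
                }
            )
    return pd.DataFrame(rows)
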