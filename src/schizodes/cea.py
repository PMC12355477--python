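"""Health-economic analysis layer over the simulation engine.

Each of the ten candidate first-line antipsychotics is evaluated through
every treatment sequence that starts with it (nine second-line choices,
clozapine fixed third), and a first-line result is the equally weighted
mean over those sequences.  Treatments are compared by pairwise ICERs and
ranked by net monetary benefit, NMB = QALYs x WTP - costs, across a grid of
willingness-to-pay thresholds.  Uncertainty is explored by probabilistic
sensitivity analysis (re-drawing every uncertain parameter and re-running a
reduced simulation per draw, summarised as rank probabilities) and by
one-way deterministic sensitivity analysis (tornado tables for a pair of
first-line treatments).
"""

from __future__ import annotations

import copy
import hashlib
import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import engine as eng
from .engine import TreatmentSequence, run_cohort
from .outcomes import summarise_cohort
from .params import (
    ParameterSet,
    draw_psa_parameter_set,
    get_param,
    quantity_interval,
    with_param,
)

logger = logging.getLogger("schizodes")

_SUMMARY_COLUMNS = [
    "years_stable",
    "qalys_excl_se",
    "qaly_loss_cardiometabolic",
    "qaly_loss_other_se",
    "qalys_undiscounted",
    "qalys_discounted",
    "total_cost_discounted",
    "total_cost_undiscounted",
    "cost_drug",
    "cost_stable_care",
    "cost_relapse",
    "cost_se_management",
    "cost_cardiometabolic",
    "cost_death",
]


@dataclass
class CEAResult:
    """Aggregate outcomes per first-line treatment plus provenance."""

    by_first_line: pd.DataFrame  # index: treatment; mean outcomes + MC SEs
    per_sequence: pd.DataFrame  # index: sequence label
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def qalys(self) -> pd.Series:
        return self.by_first_line["qalys_discounted"]

    @property
    def costs(self) -> pd.Series:
        return self.by_first_line["total_cost_discounted"]


@dataclass
class RankDistribution:
    """P(treatment attains rank) at one willingness-to-pay threshold."""

    wtp: float
    probs: pd.DataFrame  # index: treatment; columns: rank 1..K

    def check_doubly_stochastic(self, tol: float = 1e-9) -> float:
        """Largest deviation of any row or column sum from 1."""
        rows = np.abs(self.probs.sum(axis=1).to_numpy() - 1.0)
        cols = np.abs(self.probs.sum(axis=0).to_numpy() - 1.0)
        return float(max(rows.max(), cols.max()))


def parameter_set_hash(pset: ParameterSet) -> str:
    blob = yaml.safe_dump(pset.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Sequences and aggregation
# ---------------------------------------------------------------------------

def enumerate_sequences(first_line_set: Sequence[str]) -> List[TreatmentSequence]:
    """All ordered (first, second) pairs of distinct treatments; n(n-1)
    sequences for n candidates (90 for the ten-drug comparison)."""
    names = list(first_line_set)
    if len(set(names)) != len(names):
        raise ValueError("duplicate treatment names in first-line set")
    if len(names) < 2:
        raise ValueError("need at least two treatments to form a sequence")
    return [TreatmentSequence(a, b) for a, b in permutations(names, 2)]


def run_sequences(
    pset: ParameterSet,
    sequences: List[TreatmentSequence],
    n_patients: Optional[int] = None,
    n_replications: Optional[int] = None,
    start_line: int = 1,
    initial_failures: int = 0,
    collect_trajectories: bool = False,
) -> Tuple[pd.DataFrame, list]:
    """Per-sequence mean outcomes (equal patient weighting within sequence)."""
    cohort = eng.baseline_cohort(pset, n_patients if n_patients is not None else pset.sim.n_patients)
    rows = []
    all_trajs = []
    for seq in sequences:
        trajs = run_cohort(
            pset, seq, cohort=cohort, n_patients=n_patients,
            n_replications=n_replications, start_line=start_line,
            initial_failures=initial_failures,
        )
        df = summarise_cohort(trajs, pset)
        mean = df[_SUMMARY_COLUMNS].mean()
        se = df[_SUMMARY_COLUMNS].std(ddof=1) / math.sqrt(len(df))
        row = mean.to_dict()
        row.update({f"se_{k}": v for k, v in se.items()})
        row["sequence"] = seq.label()
        row["first_line"] = seq.first_line
        row["n_trajectories"] = len(df)
        rows.append(row)
        if collect_trajectories:
            all_trajs.extend(trajs)
    return pd.DataFrame(rows).set_index("sequence"), all_trajs


def aggregate_first_line(per_sequence: pd.DataFrame) -> pd.DataFrame:
    """First-line outcomes: simple average over the sequences sharing that
    first line, equally weighted."""
    grouped = per_sequence.groupby("first_line")
    means = grouped[_SUMMARY_COLUMNS].mean()
    # Monte-Carlo SE of the equally weighted mean of sequence means
    k = grouped.size()
    se = per_sequence.groupby("first_line")[[f"se_{c}" for c in _SUMMARY_COLUMNS]].apply(
        lambda g: np.sqrt((g**2).sum()) / len(g)
    )
    return means.join(se)


def run_base_case(
    pset: ParameterSet,
    n_patients: Optional[int] = None,
    n_replications: Optional[int] = None,
    sequences: Optional[List[TreatmentSequence]] = None,
    start_line: int = 1,
    initial_failures: int = 0,
    label: str = "base_case",
    collect_trajectories: bool = False,
) -> CEAResult:
    """Simulate every sequence and aggregate to first-line results."""
    if sequences is None:
        sequences = enumerate_sequences(pset.first_line_names)
    per_seq, trajs = run_sequences(
        pset, sequences, n_patients, n_replications, start_line, initial_failures,
        collect_trajectories,
    )
    by_fl = aggregate_first_line(per_seq)
    res = CEAResult(
        by_first_line=by_fl,
        per_sequence=per_seq,
        meta={
            "label": label,
            "parameter_hash": parameter_set_hash(pset),
            "seed": pset.sim.master_seed,
            "n_patients": n_patients if n_patients is not None else pset.sim.n_patients,
            "n_replications": n_replications
            if n_replications is not None
            else pset.sim.n_replications,
            "n_sequences": len(sequences),
        },
    )
    if collect_trajectories:
        res.meta["trajectories"] = trajs
    return res


# ---------------------------------------------------------------------------
# NMB, ICERs, ranking
# ---------------------------------------------------------------------------

def net_monetary_benefit(qalys: float, costs: float, wtp: float) -> float:
    """NMB = QALYs x WTP - costs (GBP)."""
    if wtp < 0:
        raise ValueError(f"wtp must be non-negative, got {wtp}")
    return qalys * wtp - costs


def icer_table(results: CEAResult) -> pd.DataFrame:
    """Pairwise incremental cost-effectiveness ratios.

    For every ordered pair the arm with lower QALYs is the reference.
    ``label`` is "icer" for a regular ratio, "dominant" when the comparator
    also costs less, and "undefined" when the QALY difference is zero.
    """
    q, c = results.qalys, results.costs
    names = list(q.index)
    if len(names) < 2:
        raise ValueError("need at least two treatments for ICERs")
    rows = []
    for a, b in permutations(names, 2):
        if q[a] > q[b] or (q[a] == q[b] and a > b):
            continue  # keep the lower-QALY arm as reference
        ref, comp = a, b
        dq, dc = q[comp] - q[ref], c[comp] - c[ref]
        if dq == 0.0:
            label, icer = "undefined", math.nan
        elif dc < 0:
            label, icer = "dominant", math.nan
        else:
            label, icer = "icer", dc / dq
        rows.append(
            {"reference": ref, "comparator": comp, "delta_qalys": dq,
             "delta_costs": dc, "icer": icer, "label": label}
        )
    return pd.DataFrame(rows)


def rank_treatments(
    results: CEAResult, wtp_grid: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Deterministic NMB ranking per WTP (long format).

    Ties broken by lower cost, then lexicographic name.
    """
    if wtp_grid is None:
        wtp_grid = [0.0, 20000.0, 100000.0]
    q, c = results.qalys, results.costs
    rows = []
    for wtp in wtp_grid:
        nmb = {t: net_monetary_benefit(q[t], c[t], wtp) for t in q.index}
        order = sorted(q.index, key=lambda t: (-nmb[t], c[t], t))
        for rank, t in enumerate(order, start=1):
            rows.append({"wtp": wtp, "treatment": t, "nmb": nmb[t], "rank": rank})
    return pd.DataFrame(rows)


def rank_crossovers(rank_table: pd.DataFrame) -> List[float]:
    """WTP grid points at which the ranking differs from the previous point
    (empty list = ranking stable across the grid)."""
    crossings = []
    prev = None
    for wtp, grp in rank_table.groupby("wtp", sort=True):
        order = tuple(grp.sort_values("rank")["treatment"])
        if prev is not None and order != prev:
            crossings.append(float(wtp))
        prev = order
    return crossings


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def rank_distribution_from_orders(
    orders: List[List[str]], treatments: List[str], wtp: float
) -> RankDistribution:
    k = len(treatments)
    counts = pd.DataFrame(0.0, index=treatments, columns=range(1, k + 1))
    for order in orders:
        for rank, t in enumerate(order, start=1):
            counts.loc[t, rank] += 1.0
    return RankDistribution(wtp=wtp, probs=counts / max(len(orders), 1))


def run_psa(
    pset: ParameterSet,
    n_draws: Optional[int] = None,
    wtp_grid: Optional[Sequence[float]] = None,
    n_patients: Optional[int] = None,
    n_replications: Optional[int] = None,
) -> Dict[float, RankDistribution]:
    """PSA: redraw all uncertain parameters per draw, re-run a reduced
    simulation of every sequence, and rank first lines by NMB.

    Returns a doubly stochastic rank-probability matrix per WTP.
    """
    if not pset.uncertainty:
        raise ValueError("PSA requires a non-empty uncertainty map")
    sim = pset.sim
    n_draws = n_draws if n_draws is not None else sim.n_psa_draws
    wtps = list(wtp_grid) if wtp_grid is not None else [sim.base_wtp]
    n_pat = n_patients if n_patients is not None else sim.psa_n_patients
    n_rep = n_replications if n_replications is not None else sim.psa_n_replications
    treatments = pset.first_line_names
    sequences = enumerate_sequences(treatments)

    param_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((sim.master_seed, 777000111)))
    )
    orders: Dict[float, List[List[str]]] = {w: [] for w in wtps}
    for d in range(n_draws):
        drawn = draw_psa_parameter_set(pset, param_rng)
        # independent simulation noise per draw, CRN across sequences within
        object.__setattr__(drawn.sim, "master_seed", (sim.master_seed + 7919 * (d + 1)) % (2**31))
        res = run_base_case(drawn, n_patients=n_pat, n_replications=n_rep,
                            sequences=sequences, label=f"psa_draw_{d}")
        q, c = res.qalys, res.costs
        for w in wtps:
            nmb = {t: net_monetary_benefit(q[t], c[t], w) for t in treatments}
            orders[w].append(sorted(treatments, key=lambda t: (-nmb[t], c[t], t)))
    return {w: rank_distribution_from_orders(orders[w], treatments, w) for w in wtps}


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis (tornado)
# ---------------------------------------------------------------------------

def dsa_bounds(pset: ParameterSet, path: str, spread: float = 0.2) -> Optional[Tuple[float, float]]:
    """Low/high DSA values: the uncertainty distribution's central 95%
    interval when one exists, otherwise +/-20% of the point estimate."""
    if path in pset.uncertainty and pset.uncertainty[path].distribution != "fixed":
        return quantity_interval(pset.uncertainty[path])
    try:
        base = get_param(pset, path)
    except (KeyError, AttributeError):
        return None
    if not isinstance(base, (int, float)):
        return None
    if base == 0.0:
        return None
    lo, hi = base * (1 - spread), base * (1 + spread)
    if 0.0 <= base <= 1.0 and "prob" in path:
        hi = min(hi, 1.0)
    return (lo, hi)


def _pair_outcome(
    pset: ParameterSet,
    pair: Tuple[str, str],
    wtp: float,
    n_patients: int,
    n_replications: int,
) -> Tuple[float, float]:
    """(incremental NMB, incremental QALYs) of pair[0] vs pair[1]."""
    a, b = pair
    seqs = [s for s in enumerate_sequences(pset.first_line_names) if s.first_line in (a, b)]
    res = run_base_case(pset, n_patients=n_patients, n_replications=n_replications,
                        sequences=seqs, label=f"dsa_{a}_vs_{b}")
    q, c = res.qalys, res.costs
    dnmb = net_monetary_benefit(q[a], c[a], wtp) - net_monetary_benefit(q[b], c[b], wtp)
    return dnmb, q[a] - q[b]


def run_dsa(
    pset: ParameterSet,
    pair: Tuple[str, str],
    wtp: Optional[float] = None,
    parameters: Optional[Sequence[str]] = None,
    n_patients: Optional[int] = None,
    n_replications: Optional[int] = None,
) -> pd.DataFrame:
    """One-way DSA over model parameters for a pair of first-line
    treatments; rows sorted by the NMB swing (tornado order)."""
    sim = pset.sim
    wtp = wtp if wtp is not None else sim.base_wtp
    n_pat = n_patients if n_patients is not None else sim.psa_n_patients
    n_rep = n_replications if n_replications is not None else sim.psa_n_replications
    paths = list(parameters) if parameters is not None else sorted(pset.uncertainty)

    base_nmb, base_dq = _pair_outcome(pset, pair, wtp, n_pat, n_rep)
    rows = []
    for path in paths:
        bounds = dsa_bounds(pset, path)
        if bounds is None:
            logger.info("DSA: skipping parameter %s (no bounds derivable)", path)
            continue
        lo, hi = bounds
        nmb_lo, dq_lo = _pair_outcome(with_param(pset, path, lo), pair, wtp, n_pat, n_rep)
        nmb_hi, dq_hi = _pair_outcome(with_param(pset, path, hi), pair, wtp, n_pat, n_rep)
        rows.append(
            {
                "parameter": path, "low": lo, "high": hi,
                "inc_nmb_low": nmb_lo, "inc_nmb_high": nmb_hi,
                "inc_qalys_low": dq_lo, "inc_qalys_high": dq_hi,
                "nmb_swing": abs(nmb_hi - nmb_lo),
                "qalys_swing": abs(dq_hi - dq_lo),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("nmb_swing", ascending=False).reset_index(drop=True)
    df.attrs["base_inc_nmb"] = base_nmb
    df.attrs["base_inc_qalys"] = base_dq
    return df


# ---------------------------------------------------------------------------
# Scenario analysis
# ---------------------------------------------------------------------------

SCENARIO_AXES = {
    "horizon", "annual_discount_rate", "treatment_set", "line_context",
    "n_patients", "n_replications",
}


def run_scenario(
    pset: ParameterSet,
    overrides: Dict[str, object],
    scenario_id: str = "scenario",
) -> CEAResult:
    """Re-run the analysis under declared scenario overrides only.

    ``line_context="second"`` evaluates each drug as second-line treatment:
    patients enter with one prior failure on line 2 and the next switch goes
    straight to clozapine.
    """
    unknown = set(overrides) - SCENARIO_AXES
    if unknown:
        raise ValueError(f"not a scenario axis: {sorted(unknown)}")
    new = copy.deepcopy(pset)
    if "horizon" in overrides:
        object.__setattr__(new.sim, "horizon", float(overrides["horizon"]))
    if "annual_discount_rate" in overrides:
        object.__setattr__(new.sim, "annual_discount_rate", float(overrides["annual_discount_rate"]))
    treatments = overrides.get("treatment_set", new.first_line_names)
    start_line, initial_failures = 1, 0
    if overrides.get("line_context", "first") == "second":
        sequences = [TreatmentSequence(t, None) for t in treatments]
        start_line, initial_failures = 2, 1
    else:
        sequences = enumerate_sequences(list(treatments))
    res = run_base_case(
        new,
        n_patients=overrides.get("n_patients"),
        n_replications=overrides.get("n_replications"),
        sequences=sequences,
        start_line=start_line,
        initial_failures=initial_failures,
        label=scenario_id,
    )
    res.meta["overrides"] = {k: v for k, v in overrides.items()}
    return res
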