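"""Model parameter schema: definition, loading, validation and PSA resampling.

The full model configuration is one hierarchical YAML file (see
``schizodes/params/illustrative_uk.yaml``) grouping treatment attribute
profiles, epidemiological parameters, risk-equation coefficients, a life
table, utility weights, unit costs, baseline cohort summary statistics,
simulation settings and an uncertainty map for probabilistic sensitivity
analysis.

Field-level domain constraints (a probability outside [0, 1], a negative
cost) are enforced at parse time by pydantic and raise errors naming the
offending path.  Cross-field semantic invariants (adherence shares summing
to one, agranulocytosis restricted to clozapine, exactly one clozapine
profile) are checked by :func:`validate_parameter_set`, which returns a
report rather than raising, so that deliberately broken sets can be
constructed and inspected in tests.
"""

from __future__ import annotations

import copy
import io
import logging
import math
import re
from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

logger = logging.getLogger("schizodes")

SCHEMA_VERSION = 1

#: Metabolic markers tracked on every patient (units: kg/m2, mmol/L x4, mmHg).
METABOLIC_MARKERS = (
    "bmi",
    "total_cholesterol",
    "hdl",
    "triglyceride",
    "glucose",
    "sbp",
)

#: Short-term side-effects, resolving within ``short_term_se_duration`` years.
SHORT_TERM_SES = ("agranulocytosis", "eps", "sedation", "sexual_dysfunction", "weight_gain")

#: Permanent conditions acquired during simulation.
CHRONIC_CONDITIONS = ("post_chd", "post_stroke", "diabetes", "tardive_dyskinesia")

#: Conditions carrying a utility decrement.
DECREMENT_CONDITIONS = SHORT_TERM_SES + CHRONIC_CONDITIONS

#: Events with an additional probability of death at occurrence.
ACUTE_FATAL_EVENTS = ("agranulocytosis", "chd", "stroke")

RISK_OUTCOMES = ("chd", "stroke", "diabetes")

ADHERENCE_LEVELS = ("full", "partial", "none")


class ParameterError(ValueError):
    """A parameter file failed schema or domain validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


def _check_prob_map(v: Dict[str, float], what: str) -> Dict[str, float]:
    for k, p in v.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{what}[{k}] = {p} outside [0, 1]")
    return v


class TreatmentProfile(_Model):
    """Attributes of one antipsychotic (relapse efficacy, tolerability,
    metabolic impact, short-term side-effect incidences, drug cost)."""

    name: str
    route: Literal["oral", "lai"] = "oral"
    relapse_risk_ratio: float = Field(gt=0)
    annual_discontinuation_prob: float = Field(ge=0, le=1)
    annual_td_prob: float = Field(ge=0, le=1)
    metabolic_deltas: Dict[str, float] = Field(default_factory=dict)
    short_term_se_probs: Dict[str, float] = Field(default_factory=dict)
    annual_drug_cost: float = Field(ge=0)
    is_clozapine: bool = False

    @field_validator("metabolic_deltas")
    @classmethod
    def _known_markers(cls, v):
        unknown = set(v) - set(METABOLIC_MARKERS)
        if unknown:
            raise ValueError(f"unknown metabolic markers {sorted(unknown)}")
        return v

    @field_validator("short_term_se_probs")
    @classmethod
    def _se_probs(cls, v):
        unknown = set(v) - set(SHORT_TERM_SES)
        if unknown:
            raise ValueError(f"unknown short-term side-effects {sorted(unknown)}")
        return _check_prob_map(v, "short_term_se_probs")


class EpidemiologyParams(_Model):
    annual_relapse_prob_no_treatment: float = Field(ge=0, lt=1)
    remission_duration: float = Field(default=0.5, gt=0)
    switch_prob_after_relapse: float = Field(default=0.5, ge=0, le=1)
    adherence_distribution: Dict[str, float] = Field(
        default_factory=lambda: {"full": 0.5, "partial": 0.3, "none": 0.2}
    )
    #: Interpolation weight w per adherence level: the treated relapse hazard
    #: modifier is RR + w * (1 - RR), so w=0 gives the full treatment effect
    #: and w=1 the untreated hazard.  The implied multiplier on the fully
    #: adherent hazard, (RR + w*(1-RR))/RR, is >= 1 and equals 1 at w=0.
    adherence_relapse_weights: Dict[str, float] = Field(
        default_factory=lambda: {"full": 0.0, "partial": 0.5, "none": 1.0}
    )
    smr_schizophrenia: float = Field(default=1.0, gt=0)
    case_fatality: Dict[str, float] = Field(default_factory=dict)

    @field_validator("adherence_distribution", "adherence_relapse_weights", "case_fatality")
    @classmethod
    def _probs(cls, v, info):
        return _check_prob_map(v, info.field_name)


class UtilityParams(_Model):
    u_stable: float = Field(ge=0, le=1)
    u_relapse: float = Field(ge=0, le=1)
    decrement_per_condition: Dict[str, float] = Field(default_factory=dict)
    short_term_se_duration: float = Field(default=0.25, gt=0)

    @field_validator("decrement_per_condition")
    @classmethod
    def _decrements(cls, v):
        unknown = set(v) - set(DECREMENT_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        for k, d in v.items():
            if d < 0:
                raise ValueError(f"decrement_per_condition[{k}] = {d} negative")
        return v


class CostParams(_Model):
    """Unit costs, NHS perspective, in the labelled currency year (GBP)."""

    annual_stable_care_cost: float = Field(ge=0)
    relapse_episode_cost: float = Field(ge=0)
    #: "per_episode": lump sum at each relapse; "per_year": the relapse cost
    #: is an annual rate accrued while in the relapse state instead.
    relapse_cost_dialect: Literal["per_episode", "per_year"] = "per_episode"
    per_event_acute_cost: Dict[str, float] = Field(default_factory=dict)
    annual_chronic_cost: Dict[str, float] = Field(default_factory=dict)
    death_cost: float = Field(default=0.0, ge=0)
    currency_year: int = 2020

    @field_validator("per_event_acute_cost", "annual_chronic_cost")
    @classmethod
    def _nonneg(cls, v, info):
        for k, c in v.items():
            if c < 0:
                raise ValueError(f"{info.field_name}[{k}] = {c} negative")
        return v


class SimulationConfig(_Model):
    n_patients: int = Field(default=1000, ge=1)
    n_replications: int = Field(default=100, ge=1)
    horizon: float = Field(default=10.0, gt=0)
    annual_discount_rate: float = Field(default=0.035, ge=0, lt=1)
    wtp_grid: List[float] = Field(
        default_factory=lambda: [float(w) for w in range(0, 100001, 10000)]
    )
    base_wtp: float = Field(default=20000.0, ge=0)
    n_psa_draws: int = Field(default=1000, ge=1)
    #: Reduced per-draw simulation size for PSA.
    psa_n_patients: int = Field(default=200, ge=1)
    psa_n_replications: int = Field(default=20, ge=1)
    master_seed: int = 20200
    common_random_numbers: bool = True
    #: Whether a relapse without a treatment switch still counts towards the
    #: two consecutive failures that trigger clozapine.
    nonswitch_relapse_counts_as_failure: bool = True
    #: Whether a patient who discontinued and then relapsed without switching
    #: restarts the current-line treatment at remission.
    restart_treatment_at_remission: bool = True
    max_events_per_trajectory: int = 10000
    #: Tie-break priority for simultaneous events (earlier = first).
    tie_priority: List[str] = Field(
        default_factory=lambda: [
            "death",
            "chd",
            "stroke",
            "diabetes",
            "relapse",
            "remission",
            "discontinuation",
            "tardive_dyskinesia",
        ]
    )


class UncertainQuantity(_Model):
    """Point estimate plus the sampling distribution used in PSA."""

    distribution: Literal["beta", "gamma", "lognormal", "normal", "fixed"]
    #: beta: {alpha, beta}; gamma: {shape, scale}; lognormal: {mu, sigma}
    #: (parameters of the underlying normal); normal: {mu, sd}; fixed: {}.
    params: Dict[str, float] = Field(default_factory=dict)


class RiskTerm(_Model):
    covariate: str
    coef: float
    transform: Literal["identity", "log"] = "identity"


class RiskEquation(_Model):
    """One published multivariable risk equation (e.g. a Framingham score).

    ``logistic`` form: risk = expit(intercept + sum(coef * transform(x))).
    ``cox`` form: risk = 1 - baseline_survival ** exp(lp - mean_lp).
    ``horizon_years`` is the horizon over which the published score predicts
    the event probability (e.g. 10 for CHD/stroke, 8 for diabetes).
    """

    variant: str = ""
    form: Literal["logistic", "cox"] = "logistic"
    horizon_years: float = Field(gt=0)
    intercept: float = 0.0
    baseline_survival: float = Field(default=0.95, gt=0, le=1)
    mean_lp: float = 0.0
    terms: List[RiskTerm] = Field(default_factory=list)


class RiskCoefficients(_Model):
    chd: RiskEquation
    stroke: RiskEquation
    diabetes: RiskEquation

    def equation(self, outcome: str) -> RiskEquation:
        try:
            return getattr(self, outcome)
        except AttributeError:
            raise KeyError(f"unknown risk outcome {outcome!r}") from None


class LifeTable(_Model):
    """Annual death probabilities q(age, sex); q at max_age is forced to 1."""

    ages: List[int]
    qx: Dict[str, List[float]]  # sex -> q per age, aligned with ages

    @field_validator("qx")
    @classmethod
    def _q_domain(cls, v):
        for sex, qs in v.items():
            for q in qs:
                if not (0.0 <= q <= 1.0):
                    raise ValueError(f"life table q for {sex} outside [0, 1]")
        return v

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def annual_q(self, sex: str) -> np.ndarray:
        q = np.asarray(self.qx[sex], dtype=float)
        q = q.copy()
        q[-1] = 1.0  # convention: certain death in the final table year
        return q

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Read a life table from CSV with columns age, sex, qx."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        missing = {"age", "sex", "qx"} - set(df.columns)
        if missing:
            raise ParameterError(f"life table CSV missing columns {sorted(missing)}")
        ages = sorted(df["age"].unique().tolist())
        qx = {}
        for sex, sub in df.groupby("sex"):
            sub = sub.sort_values("age")
            if sub["age"].tolist() != ages:
                raise ParameterError(f"life table ages for sex {sex!r} not aligned")
            qx[str(sex)] = sub["qx"].tolist()
        return cls(ages=[int(a) for a in ages], qx=qx)


class ContinuousTrait(_Model):
    mean: float
    sd: float = Field(ge=0)
    lower: float
    upper: float


class BaselineSummary(_Model):
    """Summary-level description of the entry cohort: truncated-normal
    moments per continuous trait, category probabilities per categorical."""

    continuous: Dict[str, ContinuousTrait]
    categorical: Dict[str, Dict[str, float]]

    @field_validator("categorical")
    @classmethod
    def _cat_probs(cls, v):
        for name, cats in v.items():
            _check_prob_map(cats, f"categorical[{name}]")
        return v


class ParameterSet(_Model):
    """Complete model configuration."""

    schema_version: int = SCHEMA_VERSION
    treatments: List[TreatmentProfile]
    epidemiology: EpidemiologyParams
    utilities: UtilityParams
    costs: CostParams
    risk_coefficients: RiskCoefficients
    life_table: LifeTable
    baseline: BaselineSummary
    sim: SimulationConfig = Field(default_factory=SimulationConfig)
    uncertainty: Dict[str, UncertainQuantity] = Field(default_factory=dict)

    def treatment(self, name: str) -> TreatmentProfile:
        for t in self.treatments:
            if t.name == name:
                return t
        raise KeyError(f"no treatment named {name!r}")

    @property
    def clozapine(self) -> TreatmentProfile:
        for t in self.treatments:
            if t.is_clozapine:
                return t
        raise KeyError("no clozapine profile in parameter set")

    @property
    def first_line_names(self) -> List[str]:
        return [t.name for t in self.treatments if not t.is_clozapine]


# ---------------------------------------------------------------------------
# Loading / serialisation
# ---------------------------------------------------------------------------

def builtin_config_path(name: str) -> Path:
    """Path of a parameter file shipped with the package.

    ``name`` is e.g. ``"illustrative_uk"`` or ``"minimal_test"``.
    """
    fname = name if name.endswith((".yaml", ".csv")) else name + ".yaml"
    return Path(str(resources.files("schizodes").joinpath("params", fname)))


def _log_defaults(model: BaseModel, raw: dict, prefix: str = "") -> None:
    for fname, finfo in type(model).model_fields.items():
        if fname not in raw:
            if finfo.is_required():
                continue
            logger.info("parameter defaulted: %s%s = %r", prefix, fname,
                        getattr(model, fname))
        else:
            sub = getattr(model, fname)
            if isinstance(sub, BaseModel) and isinstance(raw[fname], dict):
                _log_defaults(sub, raw[fname], prefix=f"{prefix}{fname}.")


def load_parameter_set(path) -> ParameterSet:
    """Load and fully validate a parameter file.

    A ``life_table_csv`` entry (path relative to the config file) is
    materialised into the inline ``life_table`` block, so a loaded set is
    self-contained and round-trips through :func:`save_parameter_set`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    raw = dict(raw)
    csv_ref = raw.pop("life_table_csv", None)
    if csv_ref is not None and "life_table" not in raw:
        lt = LifeTable.from_csv(path.parent / csv_ref)
        raw["life_table"] = lt.model_dump()
    try:
        pset = ParameterSet.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ParameterError(f"{path}: {msgs}") from exc
    _log_defaults(pset, raw)
    report = validate_parameter_set(pset)
    if report:
        raise ParameterError(f"{path}: " + "; ".join(report))
    return pset


def save_parameter_set(pset: ParameterSet, path) -> None:
    """Serialise a parameter set back to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(pset.model_dump(mode="json"), fh, sort_keys=False)


def loads_parameter_set(text: str) -> ParameterSet:
    """Parse a parameter set from a YAML string (no life-table indirection)."""
    raw = yaml.safe_load(io.StringIO(text))
    return ParameterSet.model_validate(raw)


# ---------------------------------------------------------------------------
# Semantic validation
# ---------------------------------------------------------------------------

def validate_parameter_set(pset: ParameterSet) -> List[str]:
    """Check cross-field invariants; return a list of violations (empty iff
    the set is valid).  Field-level domain errors are caught earlier, at
    parse time."""
    report: List[str] = []
    clo = [t.name for t in pset.treatments if t.is_clozapine]
    if len(clo) != 1:
        report.append(f"expected exactly one clozapine profile, found {len(clo)}")
    for t in pset.treatments:
        if not t.is_clozapine and t.short_term_se_probs.get("agranulocytosis", 0.0) > 0:
            report.append(
                f"treatments[{t.name}].short_term_se_probs.agranulocytosis > 0 "
                "on a non-clozapine profile"
            )
    names = [t.name for t in pset.treatments]
    if len(set(names)) != len(names):
        report.append("duplicate treatment names")

    epi = pset.epidemiology
    share = sum(epi.adherence_distribution.values())
    if abs(share - 1.0) > 1e-9:
        report.append(f"adherence_distribution shares sum to {share:.6g}, expected 1")
    for lvl in epi.adherence_distribution:
        if lvl not in epi.adherence_relapse_weights:
            report.append(f"adherence level {lvl!r} has no relapse weight")
    w_full = epi.adherence_relapse_weights.get("full")
    if w_full is not None and w_full != 0.0:
        report.append("adherence_relapse_weights.full must be 0 (full effect)")
    for ev in ACUTE_FATAL_EVENTS:
        if ev not in epi.case_fatality:
            report.append(f"case_fatality missing event {ev!r}")

    u = pset.utilities
    if not (u.u_relapse <= u.u_stable):
        report.append(f"u_relapse ({u.u_relapse}) exceeds u_stable ({u.u_stable})")

    for name, trait in pset.baseline.continuous.items():
        if trait.lower >= trait.upper:
            report.append(f"baseline.continuous[{name}] bounds not ordered")
        if not (trait.lower <= trait.mean <= trait.upper):
            report.append(f"baseline.continuous[{name}] mean outside bounds")
    for name, cats in pset.baseline.categorical.items():
        s = sum(cats.values())
        if abs(s - 1.0) > 1e-9:
            report.append(
                f"baseline.categorical[{name}] probabilities sum to {s:.6g}, expected 1"
            )
    if "adherence" in pset.baseline.categorical:
        for lvl in pset.baseline.categorical["adherence"]:
            if lvl not in epi.adherence_relapse_weights:
                report.append(f"baseline adherence level {lvl!r} has no relapse weight")

    # risk-equation covariates must resolve against patient profile fields
    from .population import PROFILE_COVARIATES  # local import to avoid a cycle

    for outcome in RISK_OUTCOMES:
        eq = pset.risk_coefficients.equation(outcome)
        for term in eq.terms:
            if term.covariate not in PROFILE_COVARIATES:
                report.append(
                    f"risk_coefficients.{outcome}: unknown covariate {term.covariate!r}"
                )

    ages = pset.life_table.ages
    if ages != list(range(ages[0], ages[-1] + 1)):
        report.append("life table ages not contiguous")
    for path in pset.uncertainty:
        try:
            get_param(pset, path)
        except (KeyError, AttributeError):
            report.append(f"uncertainty path {path!r} does not resolve")
    return report


# ---------------------------------------------------------------------------
# Parameter-path addressing (used by PSA and DSA)
# ---------------------------------------------------------------------------

_SEG = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)(?:\[([^\]]+)\])?")


def _walk(pset: ParameterSet, path: str) -> Tuple[object, str]:
    """Resolve a dotted path; returns (parent container, final key)."""
    parts = path.split(".")
    obj: object = pset
    for i, part in enumerate(parts):
        m = _SEG.fullmatch(part)
        if not m:
            raise KeyError(f"malformed path segment {part!r} in {path!r}")
        attr, key = m.group(1), m.group(2)
        last = i == len(parts) - 1
        if last and key is None:
            return obj, attr
        obj = obj[attr] if isinstance(obj, dict) else getattr(obj, attr)
        if key is not None:
            if attr == "treatments":
                matches = [t for t in obj if t.name == key]  # type: ignore[union-attr]
                if not matches:
                    raise KeyError(f"no treatment named {key!r} in {path!r}")
                obj = matches[0]
                if last:
                    raise KeyError(f"path {path!r} ends on a treatment, not a field")
            elif isinstance(obj, dict):
                if last:
                    return obj, key
                obj = obj[key]
            else:
                raise KeyError(f"cannot index {attr!r} in {path!r}")
    raise KeyError(f"empty path {path!r}")


def get_param(pset: ParameterSet, path: str) -> float:
    parent, key = _walk(pset, path)
    value = parent[key] if isinstance(parent, dict) else getattr(parent, key)
    if isinstance(parent, dict) and key not in parent:
        raise KeyError(path)
    return value


def set_param(pset: ParameterSet, path: str, value: float) -> None:
    """Set a scalar parameter in place (use on a deep copy)."""
    parent, key = _walk(pset, path)
    if isinstance(parent, dict):
        if key not in parent:
            raise KeyError(path)
        parent[key] = value
    else:
        if not hasattr(parent, key):
            raise KeyError(path)
        object.__setattr__(parent, key, value)


def with_param(pset: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a deep copy of ``pset`` with one parameter replaced."""
    new = copy.deepcopy(pset)
    set_param(new, path, value)
    return new


# ---------------------------------------------------------------------------
# PSA resampling
# ---------------------------------------------------------------------------

def draw_quantity(uq: UncertainQuantity, rng: np.random.Generator) -> float:
    """One draw from an uncertain quantity's stated distribution."""
    d, p = uq.distribution, uq.params
    if d == "fixed":
        return float(p.get("value", math.nan))
    if d == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if d == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if d == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    if d == "normal":
        return float(rng.normal(p["mu"], p["sd"]))
    raise ValueError(f"unknown distribution {d!r}")


def quantity_interval(uq: UncertainQuantity, lo: float = 0.025, hi: float = 0.975):
    """Central interval of an uncertain quantity (used for DSA bounds)."""
    from scipy import stats

    d, p = uq.distribution, uq.params
    if d == "fixed":
        v = p.get("value", math.nan)
        return v, v
    if d == "beta":
        dist = stats.beta(p["alpha"], p["beta"])
    elif d == "gamma":
        dist = stats.gamma(p["shape"], scale=p["scale"])
    elif d == "lognormal":
        dist = stats.lognorm(p["sigma"], scale=math.exp(p["mu"]))
    elif d == "normal":
        dist = stats.norm(p["mu"], p["sd"])
    else:
        raise ValueError(f"unknown distribution {d!r}")
    return float(dist.ppf(lo)), float(dist.ppf(hi))


MAX_PSA_RETRIES = 100


def draw_psa_parameter_set(pset: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Independently redraw every uncertain quantity; fixed entries and all
    parameters without an uncertainty entry are unchanged.  Draws that leave
    the set invalid are resampled (bounded retries)."""
    new = copy.deepcopy(pset)
    for path in sorted(new.uncertainty):
        uq = new.uncertainty[path]
        if uq.distribution == "fixed":
            continue
        base = get_param(new, path)
        prob_like = uq.distribution == "beta" or (0.0 <= base <= 1.0 and "prob" in path)
        for _ in range(MAX_PSA_RETRIES):
            value = draw_quantity(uq, rng)
            if prob_like and not (0.0 <= value <= 1.0):
                continue
            set_param(new, path, value)
            if not validate_parameter_set(new):
                break
            set_param(new, path, base)  # cross-field violation: roll back, retry
        else:
            raise ParameterError(
                f"PSA draw for {path!r} failed domain validation after "
                f"{MAX_PSA_RETRIES} retries"
            )
    return new
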