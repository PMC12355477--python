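"""Synthetic baseline cohort generation.

The model is populated from summary-level statistics (means, standard
deviations and category probabilities of a first-episode psychosis cohort),
not from any individual-level dataset.  Continuous traits are sampled from
truncated normal distributions at the configured mean/sd within
physiological plausibility bounds; categorical traits from the configured
category probabilities.  Metabolic markers are independent by default, with
an optional Gaussian copula for joint sampling whose marginals stay exactly
truncated-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .params import BaselineSummary, METABOLIC_MARKERS

#: Continuous traits every profile carries (age plus the metabolic markers).
CONTINUOUS_TRAITS = ("age",) + METABOLIC_MARKERS

#: Covariate names a risk equation may reference.  Continuous covariates map
#: to profile attributes; the rest are 0/1 indicators derived from
#: categorical traits and history flags.
PROFILE_COVARIATES = CONTINUOUS_TRAITS + (
    "male",
    "smoker",
    "on_antihypertensive",
    "diabetes",
    "prior_chd",
    "prior_stroke",
)


class ConfigurationError(ValueError):
    """Invalid cohort-generation configuration."""


@dataclass(slots=True)
class PatientProfile:
    """One simulated patient at model entry (current values thereafter)."""

    id: int
    age: float
    sex: str
    bmi: float
    total_cholesterol: float
    hdl: float
    triglyceride: float
    glucose: float
    sbp: float
    smoking: str
    alcohol: str
    adherence_level: str
    prior_chd: bool = False
    prior_stroke: bool = False
    prior_diabetes: bool = False
    on_antihypertensive: bool = False
    #: set during simulation on diabetes onset
    diabetes: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        self.diabetes = self.diabetes or self.prior_diabetes

    def covariate(self, name: str) -> float:
        """Resolve a risk-equation covariate to its numeric value."""
        if name in CONTINUOUS_TRAITS:
            return float(getattr(self, name))
        if name == "male":
            return 1.0 if self.sex == "male" else 0.0
        if name == "smoker":
            return 1.0 if self.smoking == "current" else 0.0
        if name in ("on_antihypertensive", "diabetes", "prior_chd", "prior_stroke"):
            return 1.0 if getattr(self, name) else 0.0
        raise KeyError(f"unknown covariate {name!r}")


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Inverse CDF of N(mean, sd) truncated to [lo, hi], vectorised in u."""
    if lo >= hi:
        raise ConfigurationError(f"degenerate bounds [{lo}, {hi}]")
    if sd == 0.0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
    return mean + sd * stats.norm.ppf(fa + u * (fb - fa))


def metabolic_correlation(
    summary: BaselineSummary, correlation: Optional[np.ndarray]
) -> np.ndarray:
    """Validate (or default) the copula correlation over CONTINUOUS_TRAITS.

    ``None`` (the default) means independent sampling, i.e. the identity
    matrix.  A supplied matrix must be symmetric positive semi-definite with
    unit diagonal, ordered as CONTINUOUS_TRAITS restricted to the traits
    present in the summary.
    """
    names = [t for t in CONTINUOUS_TRAITS if t in summary.continuous]
    k = len(names)
    if correlation is None:
        return np.eye(k)
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (k, k):
        raise ConfigurationError(
            f"correlation matrix shape {corr.shape} != ({k}, {k}) for traits {names}"
        )
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ConfigurationError("correlation matrix not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ConfigurationError("correlation matrix diagonal must be 1")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ConfigurationError("correlation matrix not positive semi-definite")
    return corr


def generate_cohort(
    summary: BaselineSummary,
    n: int,
    rng: np.random.Generator,
    correlation: Optional[np.ndarray] = None,
) -> List[PatientProfile]:
    """Draw ``n`` independent baseline profiles.

    Continuous traits use the truncated-normal marginals of ``summary``;
    with a ``correlation`` matrix they are coupled through a Gaussian copula
    (identity matrix reduces exactly to independent sampling).  Categorical
    traits are sampled from their configured probabilities, independently of
    the continuous block.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    names = [t for t in CONTINUOUS_TRAITS if t in summary.continuous]
    missing = set(CONTINUOUS_TRAITS) - set(names)
    if missing:
        raise ConfigurationError(f"baseline summary missing continuous traits {sorted(missing)}")
    corr = metabolic_correlation(summary, correlation)

    # Gaussian copula: Z ~ N(0, corr), U = Phi(Z), X_j = F_j^{-1}(U_j)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    u = stats.norm.cdf(z)
    cont: Dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        t = summary.continuous[name]
        cont[name] = _truncnorm_ppf(u[:, j], t.mean, t.sd, t.lower, t.upper)

    def draw_cat(name: str, default: Dict[str, float]) -> np.ndarray:
        cats = summary.categorical.get(name, default)
        labels = list(cats.keys())
        probs = np.array([cats[c] for c in labels], dtype=float)
        return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=probs)]

    sex = draw_cat("sex", {"male": 0.5, "female": 0.5})
    smoking = draw_cat("smoking", {"non": 1.0})
    alcohol = draw_cat("alcohol", {"none": 1.0})
    adherence = draw_cat("adherence", {"full": 1.0})

    def draw_flag(name: str) -> np.ndarray:
        cats = summary.categorical.get(name, {"no": 1.0})
        p_yes = cats.get("yes", 0.0)
        return rng.random(n) < p_yes

    prior_chd = draw_flag("prior_chd")
    prior_stroke = draw_flag("prior_stroke")
    prior_diabetes = draw_flag("prior_diabetes")
    on_antihypertensive = draw_flag("on_antihypertensive")

    return [
        PatientProfile(
            id=i,
            age=float(cont["age"][i]),
            sex=str(sex[i]),
            bmi=float(cont["bmi"][i]),
            total_cholesterol=float(cont["total_cholesterol"][i]),
            hdl=float(cont["hdl"][i]),
            triglyceride=float(cont["triglyceride"][i]),
            glucose=float(cont["glucose"][i]),
            sbp=float(cont["sbp"][i]),
            smoking=str(smoking[i]),
            alcohol=str(alcohol[i]),
            adherence_level=str(adherence[i]),
            prior_chd=bool(prior_chd[i]),
            prior_stroke=bool(prior_stroke[i]),
            prior_diabetes=bool(prior_diabetes[i]),
            on_antihypertensive=bool(on_antihypertensive[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# CSV export/import for external inspection and reproducibility
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [f.name for f in dc_fields(PatientProfile)]


def cohort_to_csv(cohort: List[PatientProfile], path) -> None:
    df = pd.DataFrame([{c: getattr(p, c) for c in _CSV_COLUMNS} for p in cohort])
    df.to_csv(path, index=False, float_format="%.17g")


def cohort_from_csv(path) -> List[PatientProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    bool_cols = ["prior_chd", "prior_stroke", "prior_diabetes", "on_antihypertensive", "diabetes"]
    out = []
    for row in df.to_dict("records"):
        kwargs = {c: row[c] for c in _CSV_COLUMNS if c in row}
        for c in bool_cols:
            kwargs[c] = bool(kwargs[c])
        out.append(PatientProfile(**kwargs))
    return out
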