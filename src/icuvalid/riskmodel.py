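"""Generic logistic risk-model engine.

ICU mortality models of the ICNARC/APACHE family are additive logistic
models: a linear predictor built from continuous physiology terms,
categorical weight maps (admission source, urgency, diagnostic category)
and score-by-diagnosis interactions, pushed through the inverse logit.
The published coefficient sets for those models are proprietary / not
reproduced here, so the engine consumes user-supplied coefficient tables
expressed as a :class:`ModelSpec` and evaluates them on an admission table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "ContinuousTerm",
    "CategoricalTerm",
    "InteractionTerm",
    "ModelSpec",
    "PredictionSet",
    "LogisticRiskModel",
    "predict",
    "apache_ii_score",
    "diagnosis_weight",
    "LOG_ODDS_CLAMP",
]

#: log-odds are clamped here before exponentiation: risks stay strictly in
#: (0, 1) while being indistinguishable from 0/1 at double precision
LOG_ODDS_CLAMP = 35.0

TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
    "sqrt": np.sqrt,
    "square": np.square,
}


@dataclass(frozen=True)
class ContinuousTerm:
    """coefficient * transform(field)."""

    field: str
    coefficient: float
    transform: str = "identity"

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")

    def contribution(self, X: pd.DataFrame) -> np.ndarray:
        vals = _require_field(X, self.field, "continuous")
        return self.coefficient * TRANSFORMS[self.transform](vals.to_numpy(float))


@dataclass(frozen=True)
class CategoricalTerm:
    """Level-weight map; a declared reference level carries weight 0."""

    field: str
    weights: tuple  # tuple of (level, weight) pairs — hashable + ordered
    reference: Optional[str] = None

    def weight_map(self) -> Dict[str, float]:
        m = dict(self.weights)
        if self.reference is not None:
            m.setdefault(self.reference, 0.0)
        return m

    def contribution(self, X: pd.DataFrame) -> np.ndarray:
        vals = _require_field(X, self.field, "categorical")
        m = self.weight_map()
        out = np.empty(len(vals))
        for i, level in enumerate(vals.astype(str)):
            if level not in m:
                raise ValueError(
                    f"categorical level {level!r} of field {self.field!r} has no "
                    "weight and no reference default"
                )
            out[i] = m[level]
        return out


@dataclass(frozen=True)
class InteractionTerm:
    """field_a (continuous) times a per-level weight of field_b (categorical)."""

    field_a: str
    field_b: str
    weights: tuple
    reference: Optional[str] = None

    def contribution(self, X: pd.DataFrame) -> np.ndarray:
        a = _require_field(X, self.field_a, "interaction").to_numpy(float)
        b = CategoricalTerm(self.field_b, self.weights, self.reference).contribution(X)
        return a * b


Term = Union[ContinuousTerm, CategoricalTerm, InteractionTerm]


def _require_field(X: pd.DataFrame, name: str, term_kind: str) -> pd.Series:
    if name not in X.columns:
        raise ValueError(f"missing field {name!r} required by {term_kind} term")
    col = X[name]
    if col.isna().any():
        raise ValueError(f"missing values in field {name!r} required by {term_kind} term")
    return col


@dataclass(frozen=True)
class ModelSpec:
    """Term layout + coefficient table of one logistic risk model.

    The link is fixed logistic: log-odds = intercept + sum of term
    contributions; risk = 1 / (1 + exp(-log-odds)).
    """

    name: str
    intercept: float = 0.0
    terms: tuple = ()

    # -- serialisation ------------------------------------------------------
    def to_json(self, path=None) -> str:
        rows: List[dict] = []
        for t in self.terms:
            if isinstance(t, ContinuousTerm):
                rows.append({"kind": "continuous", "field": t.field,
                             "coefficient": t.coefficient, "transform": t.transform})
            elif isinstance(t, CategoricalTerm):
                rows.append({"kind": "categorical", "field": t.field,
                             "weights": dict(t.weights), "reference": t.reference})
            elif isinstance(t, InteractionTerm):
                rows.append({"kind": "interaction", "field_a": t.field_a,
                             "field_b": t.field_b, "weights": dict(t.weights),
                             "reference": t.reference})
            else:  # pragma: no cover - guarded by construction
                raise TypeError(f"unknown term type {type(t)!r}")
        text = json.dumps({"name": self.name, "intercept": self.intercept, "terms": rows}, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ModelSpec":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        terms: List[Term] = []
        for row in doc.get("terms", []):
            kind = row["kind"]
            if kind == "continuous":
                terms.append(ContinuousTerm(row["field"], row["coefficient"],
                                            row.get("transform", "identity")))
            elif kind == "categorical":
                terms.append(CategoricalTerm(row["field"], tuple(row["weights"].items()),
                                             row.get("reference")))
            elif kind == "interaction":
                terms.append(InteractionTerm(row["field_a"], row["field_b"],
                                             tuple(row["weights"].items()),
                                             row.get("reference")))
            else:
                raise ValueError(f"unknown term kind {kind!r}")
        return cls(name=doc["name"], intercept=doc.get("intercept", 0.0), terms=tuple(terms))


@dataclass
class PredictionSet:
    """Paired per-admission predicted risks and observed outcomes for one model."""

    model_name: str
    admission_ids: np.ndarray
    log_odds: np.ndarray
    predicted_risk: np.ndarray
    outcome: np.ndarray  # 1 = died, 0 = survived

    def __post_init__(self):
        self.admission_ids = np.asarray(self.admission_ids)
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.predicted_risk = np.asarray(self.predicted_risk, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        n = len(self.admission_ids)
        if not (len(self.log_odds) == len(self.predicted_risk) == len(self.outcome) == n):
            raise ValueError("PredictionSet columns must have equal length")
        if len(np.unique(self.admission_ids)) != n:
            raise ValueError("duplicate admission_id in PredictionSet")
        if not np.all((self.predicted_risk > 0) & (self.predicted_risk < 1)):
            raise ValueError("predicted risks must lie strictly in (0, 1)")
        if not np.allclose(self.predicted_risk, expit(self.log_odds), atol=1e-8):
            raise ValueError("predicted_risk inconsistent with inverse-logit(log_odds)")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")

    def __len__(self) -> int:
        return len(self.admission_ids)

    @classmethod
    def from_risks(cls, model_name, admission_ids, predicted_risk, outcome) -> "PredictionSet":
        risk = np.clip(np.asarray(predicted_risk, dtype=float),
                       expit(-LOG_ODDS_CLAMP), expit(LOG_ODDS_CLAMP))
        return cls(model_name, admission_ids, logit(risk), risk, outcome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "admission_id": self.admission_ids,
                "log_odds": self.log_odds,
                "predicted_risk": self.predicted_risk,
                "outcome": self.outcome,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_name=None) -> "PredictionSet":
        df = pd.read_csv(path, dtype={"admission_id": str})
        name = model_name if model_name is not None else str(path)
        return cls(name, df["admission_id"].to_numpy(), df["log_odds"].to_numpy(),
                   df["predicted_risk"].to_numpy(), df["outcome"].to_numpy())

    def subset(self, mask_or_ids) -> "PredictionSet":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = np.isin(self.admission_ids, arr)
        return PredictionSet(self.model_name, self.admission_ids[mask],
                             self.log_odds[mask], self.predicted_risk[mask],
                             self.outcome[mask])


class LogisticRiskModel(BaseEstimator):
    """Evaluates a :class:`ModelSpec` on an admission table.

    The estimator carries externally supplied coefficients, so ``fit`` is a
    no-op provided for pipeline compatibility.
    """

    def __init__(self, spec: ModelSpec = None):
        self.spec = spec

    def fit(self, X=None, y=None) -> "LogisticRiskModel":
        if self.spec is None:
            raise ValueError("LogisticRiskModel requires a ModelSpec")
        self.spec_ = self.spec
        return self

    def predict_log_odds(self, X: pd.DataFrame) -> np.ndarray:
        spec = self.spec
        if spec is None:
            raise ValueError("LogisticRiskModel requires a ModelSpec")
        lo = np.full(len(X), float(spec.intercept))
        for term in spec.terms:
            lo += term.contribution(X)
        return np.clip(lo, -LOG_ODDS_CLAMP, LOG_ODDS_CLAMP)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.predict_log_odds(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_risk(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_risk(X) >= 0.5).astype(int)

    def predict_set(self, X: pd.DataFrame, id_col="admission_id",
                    outcome_col="hospital_mortality") -> PredictionSet:
        lo = self.predict_log_odds(X)
        outcome = X[outcome_col]
        if outcome.dtype == object:
            y = (outcome == "died").astype(int).to_numpy()
        else:
            y = outcome.to_numpy(int)
        return PredictionSet(self.spec.name, X[id_col].to_numpy(), lo, expit(lo), y)


def predict(spec: ModelSpec, record) -> tuple:
    """(log_odds, predicted_risk) for a single admission record (mapping or Series)."""
    frame = pd.DataFrame([dict(record)]) if not isinstance(record, pd.DataFrame) else record
    model = LogisticRiskModel(spec)
    lo = model.predict_log_odds(frame)
    return float(lo[0]), float(expit(lo[0]))


# ---------------------------------------------------------------------------
# APACHE II score assembly
# ---------------------------------------------------------------------------

_APACHE_AGE_BOUNDS = (45, 55, 65, 75)  # category edges: <=44, 45-54, 55-64, 65-74, >=75


def apache_ii_score(aps: int, age: float, chronic_points: int, age_point_table) -> int:
    """APACHE II score = acute physiology (0-60) + age points + chronic points (0-5).

    ``age_point_table`` supplies one integer 0-6 per age category
    (<=44, 45-54, 55-64, 65-74, >=75); the category boundaries are fixed,
    the point values are configuration.
    """
    table = list(age_point_table)
    if len(table) != 5 or any(not (0 <= int(v) <= 6) for v in table):
        raise ValueError("age_point_table must supply five integers in 0..6")
    if not 0 <= aps <= 60:
        raise ValueError(f"acute physiology score must be in 0..60, got {aps}")
    if not 0 <= chronic_points <= 5:
        raise ValueError(f"chronic health points must be in 0..5, got {chronic_points}")
    idx = int(np.searchsorted(_APACHE_AGE_BOUNDS, age, side="right"))
    return int(aps) + int(table[idx]) + int(chronic_points)


# ---------------------------------------------------------------------------
# Diagnosis weights over the hierarchy
# ---------------------------------------------------------------------------

def diagnosis_weight(code, weight_table: Dict[tuple, float]) -> float:
    """Weight of the deepest hierarchy prefix of ``code`` present in the table.

    Weight tables are keyed by tier-prefix tuples (type, system[, site
    [, process[, condition]]]).  Coding to the system tier suffices: a weight
    is guaranteed to exist at (type, system), deeper entries override it.
    """
    if code.resolution == "unmapped":
        raise ValueError("cannot assign a weight to an unmapped diagnosis code")
    for prefix in code.prefixes():
        if len(prefix) < 2:
            break
        if prefix in weight_table:
            return float(weight_table[prefix])
    raise KeyError(f"no weight at or above system tier for code prefix {code.prefix()!r}")
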