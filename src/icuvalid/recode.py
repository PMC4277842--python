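"""Harmonisation layer: location recoding, physiology-extreme imputation,
the sedation assumption, and five-tier hierarchical diagnosis mapping.

Critical-care audit databases frequently record *near*-extreme physiology
(e.g. the systolic pressure paired with the lowest diastolic, or the pH from
the blood gas with the lowest PaO2) rather than the true extreme a scoring
model needs.  Using the near-extreme directly would systematically
understate derangement, so the true extreme is imputed from the recorded
surrogates with an ordinary least-squares regression fitted on training
admissions where both were observed.

Admission diagnoses arrive in a source coding system and are mapped onto a
five-tier hierarchy (type > body system > anatomical site > process >
condition); a model weight can be assigned from the system tier downward,
so a mapping that only reaches a higher tier is degraded gracefully rather
than discarded.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "HierarchicalCode",
    "MappingTable",
    "ImputationModel",
    "ExtremeImputer",
    "recode_location",
    "fit_imputation_model",
    "impute_extreme",
    "assume_sedation",
    "map_diagnosis",
    "mapping_coverage",
    "LOCATION_CATEGORIES",
    "IMPUTATION_TARGETS",
]

# ---------------------------------------------------------------------------
# Hierarchical diagnosis coding
# ---------------------------------------------------------------------------

_TIER_ORDER = ("type_tier", "system_tier", "site_tier", "process_tier", "condition_tier")
_RESOLUTIONS = ("condition", "process", "site", "system", "unmapped")


@dataclass(frozen=True)
class HierarchicalCode:
    """One diagnosis code in the five-tier hierarchy.

    Tiers are nested: a populated lower tier requires every higher tier to be
    populated.  ``resolution`` is the deepest populated tier; a weight can be
    assigned whenever resolution is at least ``system``.  A code with no
    populated system tier resolves to ``unmapped``.
    """

    type_tier: Optional[str] = None
    system_tier: Optional[str] = None
    site_tier: Optional[str] = None
    process_tier: Optional[str] = None
    condition_tier: Optional[str] = None

    def __post_init__(self) -> None:
        tiers = [getattr(self, t) for t in _TIER_ORDER]
        seen_gap = False
        for value in tiers:
            if value is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    "tiers must be nested: a populated lower tier requires all "
                    f"higher tiers populated, got {tiers!r}"
                )
        if self.type_tier is not None and self.type_tier not in ("surgical", "nonsurgical"):
            raise ValueError(f"type_tier must be surgical/nonsurgical, got {self.type_tier!r}")

    @property
    def resolution(self) -> str:
        if self.condition_tier is not None:
            return "condition"
        if self.process_tier is not None:
            return "process"
        if self.site_tier is not None:
            return "site"
        if self.system_tier is not None:
            return "system"
        return "unmapped"

    @property
    def is_mapped(self) -> bool:
        return self.resolution != "unmapped"

    def prefix(self) -> tuple:
        """Populated tiers, outermost first — the key used for weight lookup."""
        out = []
        for t in _TIER_ORDER:
            v = getattr(self, t)
            if v is None:
                break
            out.append(v)
        return tuple(out)

    def prefixes(self) -> list:
        """All non-empty ancestors of :meth:`prefix`, deepest first."""
        full = self.prefix()
        return [full[:k] for k in range(len(full), 0, -1)]

    @classmethod
    def unmapped(cls) -> "HierarchicalCode":
        return cls()

    def to_dict(self) -> dict:
        return {t: getattr(self, t) for t in _TIER_ORDER}

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalCode":
        return cls(**{t: d.get(t) for t in _TIER_ORDER})


@dataclass
class MappingTable:
    """Source-diagnosis token -> :class:`HierarchicalCode` lookup.

    Tokens the mapper declared impossible to place in the hierarchy are
    carried as entries mapping to an unmapped code, so coverage reporting can
    partition the full source vocabulary.
    """

    entries: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for token, code in self.entries.items():
            if not isinstance(code, HierarchicalCode):
                raise TypeError(f"entry for {token!r} is not a HierarchicalCode")

    def lookup(self, token: str) -> HierarchicalCode:
        return self.entries.get(token, HierarchicalCode.unmapped())

    def to_json(self, path=None) -> str:
        doc = {
            "provenance": self.provenance,
            "entries": [dict(source=tok, **code.to_dict()) for tok, code in sorted(self.entries.items())],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "MappingTable":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        entries = {}
        for row in doc.get("entries", []):
            token = row["source"]
            if token in entries:
                raise ValueError(f"duplicate source token {token!r} in mapping table")
            entries[token] = HierarchicalCode.from_dict(row)
        return cls(entries=entries, provenance=doc.get("provenance", ""))


def map_diagnosis(token, table: MappingTable) -> HierarchicalCode:
    """Map one source diagnosis token; absent tokens resolve to ``unmapped``.

    Unmapped is a value, not an error: the exclusion cascade counts it
    downstream as an exclusion reason.
    """
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return HierarchicalCode.unmapped()
    return table.lookup(str(token))


def mapping_coverage(table: MappingTable) -> pd.DataFrame:
    """Count and percentage of source tokens per resolution tier.

    Percentages are rounded to integers (they may not sum exactly to 100).
    """
    counts = {r: 0 for r in _RESOLUTIONS}
    for code in table.entries.values():
        counts[code.resolution] += 1
    total = sum(counts.values())
    rows = []
    for r in _RESOLUTIONS:
        pct = round(100.0 * counts[r] / total) if total else 0
        rows.append({"resolution": r, "count": counts[r], "percent": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Location prior to admission
# ---------------------------------------------------------------------------

LOCATION_CATEGORIES = frozenset(
    {
        "emergency_department",
        "general_ward",
        "theatre",
        "recovery",
        "imaging",
        "high_dependency_unit",
        "other_critical_care",
        "other_hospital",
        "clinic",
        "home",
    }
)

#: categories that are temporary waypoints rather than true origins
_TRANSIENT = frozenset({"imaging", "recovery"})
_TRANSIENT_DEFAULT = {"imaging": "emergency_department", "recovery": "general_ward"}


def recode_location(location_prior, previous_location=None, dataset_version="v203"):
    """Resolve the effective location prior to critical-care admission.

    Admissions from an imaging department or from a recovery area used as a
    temporary critical-care area take their weighting from the location
    *before* that waypoint.  Older dataset versions recorded only a single
    prior location, so when ``previous_location`` is absent the most common
    true origin is assumed: emergency department for imaging, general ward
    for recovery.  All other categories pass through unchanged, making the
    recode idempotent.
    """
    if location_prior not in LOCATION_CATEGORIES:
        raise ValueError(f"unknown location category: {location_prior!r}")
    if location_prior not in _TRANSIENT:
        return location_prior
    if previous_location is not None and not (
        isinstance(previous_location, float) and math.isnan(previous_location)
    ):
        if previous_location not in LOCATION_CATEGORIES:
            raise ValueError(f"unknown location category: {previous_location!r}")
        if previous_location not in _TRANSIENT:
            return previous_location
        # previous location itself transient: fall back to the default origin
    return _TRANSIENT_DEFAULT[location_prior]


# ---------------------------------------------------------------------------
# Sedation assumption
# ---------------------------------------------------------------------------

def assume_sedation(gcs_lowest) -> str:
    """Sedation status from the lowest Glasgow Coma Score field.

    When sedation is not recorded explicitly, an admission with no lowest GCS
    during the first 24 h is assumed sedated (or paralysed and sedated); the
    presence of the score, not its value, drives the rule.
    """
    if gcs_lowest is None or (isinstance(gcs_lowest, float) and math.isnan(gcs_lowest)):
        return "sedated"
    g = int(gcs_lowest)
    if not 3 <= g <= 15:
        raise ValueError(f"Glasgow Coma Score must be in 3..15, got {gcs_lowest!r}")
    return "not_sedated"


# ---------------------------------------------------------------------------
# Regression imputation of physiology extremes
# ---------------------------------------------------------------------------

#: predictors recorded in the source data for each imputable extreme
IMPUTATION_TARGETS = {
    "lowest_sbp": ["highest_sbp", "paired_dbp_at_highest", "lowest_dbp", "paired_sbp_at_lowest"],
    "lowest_ph": ["ph_at_lowest_pao2"],
}

#: physiological clamp applied to imputed values (mmHg / pH units)
IMPUTATION_CLAMPS = {"lowest_sbp": (0.0, 300.0), "lowest_ph": (6.0, 8.0)}


@dataclass
class ImputationModel:
    """Frozen OLS coefficients for one imputation target, serialisable as JSON."""

    target: str
    predictor_names: list
    intercept: float
    slopes: list
    fit_n: int
    residual_sd: float

    def __post_init__(self) -> None:
        if self.target not in IMPUTATION_TARGETS:
            raise ValueError(f"unknown imputation target {self.target!r}")
        if len(self.predictor_names) != len(self.slopes):
            raise ValueError("predictor count must equal slope count")
        if self.fit_n < len(self.predictor_names) + 2:
            raise ValueError("fit_n must be at least predictor count + 2")

    def to_json(self, path=None) -> str:
        doc = {
            "target": self.target,
            "predictor_names": list(self.predictor_names),
            "intercept": self.intercept,
            "slopes": list(self.slopes),
            "fit_n": self.fit_n,
            "residual_sd": self.residual_sd,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ImputationModel":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(**doc)


class ExtremeImputer(BaseEstimator):
    """OLS imputer for an unrecorded physiology extreme.

    Parameters
    ----------
    target : {"lowest_sbp", "lowest_ph"}
        Which extreme to impute.  The predictor set is fixed per target:
        the recorded pressure surrogates for ``lowest_sbp``, the pH at the
        lowest PaO2 for ``lowest_ph``.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_predictors,)
    fit_n_ : int
        Number of complete training rows used.
    residual_sd_ : float
        Root mean squared residual (denominator n - p - 1).
    predictor_names_ : list of str
    """

    def __init__(self, target: str = "lowest_sbp"):
        self.target = target

    def fit(self, X: pd.DataFrame, y=None) -> "ExtremeImputer":
        if self.target not in IMPUTATION_TARGETS:
            raise ValueError(f"unknown imputation target {self.target!r}")
        predictors = IMPUTATION_TARGETS[self.target]
        cols = predictors + [self.target]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"training data missing columns: {missing}")
        data = X[cols].dropna()
        p = len(predictors)
        n = len(data)
        if n < p + 2:
            raise ValueError(f"need at least {p + 2} complete training rows, got {n}")
        design = np.column_stack([np.ones(n), data[predictors].to_numpy(float)])
        yv = data[self.target].to_numpy(float)
        beta, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
        if rank < p + 1:
            raise ValueError("degenerate (collinear) design matrix for imputation fit")
        resid = yv - design @ beta
        dof = max(n - p - 1, 1)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.fit_n_ = n
        self.residual_sd_ = float(np.sqrt(resid @ resid / dof))
        self.predictor_names_ = list(predictors)
        return self

    def predict(self, X) -> np.ndarray:
        """Linear prediction clamped to the target's physiological range."""
        if not hasattr(self, "coef_"):
            raise ValueError("ExtremeImputer is not fitted")
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame([X])
        for name in self.predictor_names_:
            if name not in frame.columns:
                raise ValueError(f"missing predictor field: {name}")
            if frame[name].isna().any():
                raise ValueError(f"missing predictor field: {name}")
        mat = frame[self.predictor_names_].to_numpy(float)
        pred = self.intercept_ + mat @ self.coef_
        lo, hi = IMPUTATION_CLAMPS[self.target]
        return np.clip(pred, lo, hi)

    def to_model(self) -> ImputationModel:
        return ImputationModel(
            target=self.target,
            predictor_names=list(self.predictor_names_),
            intercept=self.intercept_,
            slopes=[float(b) for b in self.coef_],
            fit_n=self.fit_n_,
            residual_sd=self.residual_sd_,
        )

    @classmethod
    def from_model(cls, model: ImputationModel) -> "ExtremeImputer":
        est = cls(target=model.target)
        est.intercept_ = float(model.intercept)
        est.coef_ = np.asarray(model.slopes, dtype=float)
        est.fit_n_ = int(model.fit_n)
        est.residual_sd_ = float(model.residual_sd)
        est.predictor_names_ = list(model.predictor_names)
        return est


def fit_imputation_model(training: pd.DataFrame, target: str) -> ImputationModel:
    """OLS fit of ``target`` on its fixed predictor set; see :class:`ExtremeImputer`."""
    return ExtremeImputer(target=target).fit(training).to_model()


def impute_extreme(record, model: ImputationModel):
    """Deterministic clamped linear prediction for one record or a frame of records."""
    est = ExtremeImputer.from_model(model)
    out = est.predict(record)
    return out if isinstance(record, pd.DataFrame) else float(out[0])
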