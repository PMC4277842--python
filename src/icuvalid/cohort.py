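"""Admission data model and the exclusion cascade.

The analysis cohort is an admission-level table (one row per critical-care
admission).  Admissions are removed in a fixed, documented order — records
flagged as excluded from severity-of-illness scoring, readmissions within
the same hospital stay, missing outcome, missing model inputs, and
diagnoses that cannot be mapped onto the hierarchical coding scheme — and a
record is counted only at the *first* stage that removes it, so the
resulting report reconciles exactly.

The in-memory cohort container is a pandas DataFrame with the column
dictionary in :data:`COLUMNS`; cohort files are plain CSV with a header row
and empty fields for missing values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .recode import MappingTable, map_diagnosis
from .riskmodel import PredictionSet
from .metrics import c_index, brier_score, oe_ratio

__all__ = [
    "COLUMNS",
    "EXCLUSION_STAGES",
    "EXCLUDE_REASONS",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "stratify_by_year",
    "simulate_exclusion_impact",
    "summarize_impact",
]

#: column dictionary for the admission-level cohort table
COLUMNS = {
    "admission_id": "opaque unique token",
    "unit_id": "opaque critical-care unit token",
    "year": "calendar year of admission",
    "age": "years at admission (>= 16 for included records)",
    "sex": "female | male",
    "surgical_status": "elective_scheduled | emergency_urgent | nonsurgical",
    "location_prior": "coded location category (see recode.LOCATION_CATEGORIES)",
    "previous_location": "coded location category or empty",
    "dataset_version": "v0 | v203",
    "cpr_24h": "cardiopulmonary resuscitation within 24 h prior (bool)",
    "highest_sbp": "highest systolic blood pressure, mmHg",
    "paired_dbp_at_highest": "diastolic paired with highest SBP, mmHg",
    "lowest_dbp": "lowest diastolic blood pressure, mmHg",
    "paired_sbp_at_lowest": "systolic paired with lowest DBP, mmHg",
    "ph_at_lowest_pao2": "arterial pH from the blood gas with the lowest PaO2",
    "gcs_lowest": "lowest Glasgow Coma Score 3-15, or empty (assumed sedated)",
    "physiology_score": "integer physiology score 0-100",
    "apache_score": "integer APACHE II score 0-71, or empty",
    "diagnosis_code": "source-system diagnosis token",
    "exclude_from_scoring": "flagged 'exclude from severity of illness scoring' (bool)",
    "exclude_reason": "sub-reason category for the scoring flag, or empty",
    "is_readmission": "readmission within the same acute hospital stay (bool)",
    "hospital_mortality": "died | survived | empty (missing)",
}

#: sub-reason taxonomy for the scoring-flag exclusions
EXCLUDE_REASONS = (
    "death_within_4h",
    "missing_core_physiology",
    "age_under_16",
    "primary_burn_injury",
    "high_dependency_unit",
    "post_surgical_recovery",
    "awaiting_transfer",
    "under_another_team",
    "unit_decision_not_to_score",
    "other_unspecified",
    "reason_missing",
    "unspecified",
)

EXCLUSION_STAGES = (
    "scoring_flag",
    "readmission",
    "missing_outcome",
    "missing_fields",
    "unmappable_diagnosis",
)


@dataclass
class ExclusionReport:
    """Auditable account of the cascade: stage order is fixed and reconciles."""

    total_in: int
    per_stage: List[Tuple[str, int, int]]  # (stage, removed, remaining)
    per_reason: Dict[str, int]
    total_retained: int

    def __post_init__(self):
        removed = sum(r for _, r, _ in self.per_stage)
        if self.total_in - removed != self.total_retained:
            raise ValueError("exclusion report does not reconcile")
        if any(r < 0 for _, r, _ in self.per_stage):
            raise ValueError("negative stage count")

    def to_json(self, path=None) -> str:
        doc = {
            "total_in": self.total_in,
            "per_stage": [
                {"stage": s, "removed": r, "remaining": rem} for s, r, rem in self.per_stage
            ],
            "per_reason": self.per_reason,
            "total_retained": self.total_retained,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ExclusionReport":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            total_in=doc["total_in"],
            per_stage=[(d["stage"], d["removed"], d["remaining"]) for d in doc["per_stage"]],
            per_reason=doc["per_reason"],
            total_retained=doc["total_retained"],
        )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; empty fields become missing values."""
    df = pd.read_csv(path, dtype={"admission_id": str, "unit_id": str, "diagnosis_code": str})
    for col in ("exclude_from_scoring", "is_readmission", "cpr_24h"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _missing(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        return series.isna() | (series.astype(str).str.strip() == "")
    return series.isna()


def apply_exclusions(
    records: pd.DataFrame, mapping: Optional[MappingTable] = None
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Apply the five-stage exclusion cascade in its fixed order.

    Stages: (1) the exclude-from-scoring flag; (2) readmissions within the
    same hospital stay; (3) missing hospital mortality; (4) missing age,
    location prior to admission or diagnosis code (counted once per record);
    (5) diagnosis token unmappable under ``mapping``.  A record is counted
    only at the first stage that removes it.  With ``mapping=None`` stage 5
    removes nothing.
    """
    if records["admission_id"].duplicated().any():
        dups = records.loc[records["admission_id"].duplicated(), "admission_id"].iloc[0]
        raise ValueError(f"duplicate admission_id in cohort: {dups!r}")
    total_in = len(records)
    remaining = np.ones(total_in, dtype=bool)
    per_stage: List[Tuple[str, int, int]] = []
    per_reason: Dict[str, int] = {}

    def _remove(stage: str, mask: np.ndarray) -> np.ndarray:
        hit = remaining & mask
        per_stage.append((stage, int(hit.sum()), int((remaining & ~mask).sum())))
        return hit

    # stage 1: scoring flag, with sub-reason bookkeeping
    flagged = records["exclude_from_scoring"].fillna(False).to_numpy(bool)
    hit = _remove("scoring_flag", flagged)
    if hit.any():
        reasons = records.loc[hit, "exclude_reason"]
        for reason, count in reasons.fillna("reason_missing").value_counts().items():
            reason = str(reason) if str(reason).strip() else "reason_missing"
            if reason not in EXCLUDE_REASONS:
                warnings.warn(f"unknown exclude_reason category {reason!r}; "
                              "bucketed as 'unspecified'")
                reason = "unspecified"
            per_reason[reason] = per_reason.get(reason, 0) + int(count)
    remaining &= ~hit

    # stage 2: readmissions
    readm = records["is_readmission"].fillna(False).to_numpy(bool)
    remaining &= ~_remove("readmission", readm)

    # stage 3: missing outcome
    remaining &= ~_remove("missing_outcome", _missing(records["hospital_mortality"]).to_numpy())

    # stage 4: missing age / location prior / diagnosis (union, counted once)
    miss4 = (
        _missing(records["age"]) | _missing(records["location_prior"]) | _missing(records["diagnosis_code"])
    ).to_numpy()
    remaining &= ~_remove("missing_fields", miss4)

    # stage 5: diagnosis present but unmappable under the supplied table
    if mapping is not None:
        tokens = records["diagnosis_code"]
        unmappable = np.fromiter(
            ((not _is_na(tok)) and not map_diagnosis(tok, mapping).is_mapped for tok in tokens),
            dtype=bool,
            count=total_in,
        )
    else:
        unmappable = np.zeros(total_in, dtype=bool)
    remaining &= ~_remove("unmappable_diagnosis", unmappable)

    report = ExclusionReport(
        total_in=total_in,
        per_stage=per_stage,
        per_reason=per_reason,
        total_retained=int(remaining.sum()),
    )
    return records.loc[remaining].reset_index(drop=True), report


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def stratify_by_year(records: pd.DataFrame) -> Dict[int, pd.DataFrame]:
    """Partition the cohort by calendar year of admission."""
    if records["year"].isna().any():
        raise ValueError("every record must have a year")
    return {
        int(year): group.reset_index(drop=True)
        for year, group in records.groupby("year", sort=True)
    }


# ---------------------------------------------------------------------------
# Post hoc exclusion-impact simulation
# ---------------------------------------------------------------------------

def simulate_exclusion_impact(
    records: pd.DataFrame,
    preds: PredictionSet,
    fraction_by_category: Dict[str, float],
    replications: int = 100,
    seed: Optional[int] = None,
    category_col: str = "impact_category",
) -> pd.DataFrame:
    """Percentage change in c index, Brier score and O/E ratio when random
    fractions of each patient category are excluded.

    Each replication removes, independently and without replacement, the
    stated fraction of the records belonging to each category (membership
    read from ``category_col``), recomputes the three measures on the
    surviving predictions and reports percentage changes relative to the
    full cohort.  Seeded and reproducible.

    Returns a DataFrame with one row per replication and columns
    ``delta_c_pct``, ``delta_brier_pct``, ``delta_oe_pct``.
    """
    for cat, frac in fraction_by_category.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for category {cat!r} must be in [0, 1]")
    if category_col not in records.columns:
        raise ValueError(f"records lack the category column {category_col!r}")
    id_order = pd.Index(preds.admission_ids)
    rec = records.set_index("admission_id").reindex(id_order)
    cats = rec[category_col]

    rng = np.random.default_rng(seed)
    base_c, _, _ = c_index(preds)
    base_brier = brier_score(preds)
    base_oe = oe_ratio(preds)

    members = {}
    for cat, frac in fraction_by_category.items():
        idx = np.flatnonzero((cats == cat).to_numpy())
        if len(idx) == 0 and frac > 0:
            warnings.warn(f"category {cat!r} has no eligible records; skipped")
            continue
        members[cat] = (idx, frac)

    rows = []
    for _ in range(replications):
        keep = np.ones(len(preds), dtype=bool)
        for cat, (idx, frac) in members.items():
            k = int(round(frac * len(idx)))
            if k > 0:
                keep[rng.choice(idx, size=k, replace=False)] = False
        sub = preds.subset(keep)
        try:
            c, _, _ = c_index(sub)
            delta_c = 100.0 * (c - base_c) / base_c
        except ValueError:  # a replication removed every death (or survivor)
            delta_c = np.nan
        rows.append(
            {
                "delta_c_pct": delta_c,
                "delta_brier_pct": 100.0 * (brier_score(sub) - base_brier) / base_brier,
                "delta_oe_pct": 100.0 * (oe_ratio(sub) - base_oe) / base_oe,
            }
        )
    return pd.DataFrame(rows)


def summarize_impact(deltas: pd.DataFrame) -> pd.DataFrame:
    """Range-style summary (min/mean/max and central 95%) of impact deltas."""
    out = {}
    for col in deltas.columns:
        v = deltas[col]
        out[col] = {
            "min": v.min(),
            "p2.5": v.quantile(0.025),
            "mean": v.mean(),
            "p97.5": v.quantile(0.975),
            "max": v.max(),
        }
    return pd.DataFrame(out).T
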