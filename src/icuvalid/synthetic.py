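"""Synthetic cohorts with the statistical structure the validation assumes.

The national audit databases behind this kind of external validation are
not publicly deposited, so the generator emulates the published case mix:
ages from a truncated normal (mean 57.5, SD 18.0, truncated to 16-100),
56.1% male, surgical status roughly 10.5/22.4/67.2% across
elective/emergency/non-surgical, a right-skewed integer physiology score
matched to mean 19.6 / SD 9.5 (gamma, rounded), and hospital mortality
near 29.7% driven by a logistic "true" risk model whose predictions are
well-calibrated by construction.

A competitor prediction set is derived from the true one by two separable
distortions: a linear miscalibration of the survival log-odds
(log-odds' = c + d * log-odds, reproducing the under-predicted risk and
variability pattern of a legacy score) and optional additive Gaussian
log-odds noise (information loss, which lowers discrimination — a pure
monotone distortion cannot).

A separate deterministic fixture reproduces the published exclusion
cascade exactly, record for record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .recode import HierarchicalCode, MappingTable, map_diagnosis
from .riskmodel import (
    CategoricalTerm,
    ContinuousTerm,
    InteractionTerm,
    LogisticRiskModel,
    ModelSpec,
    PredictionSet,
    LOG_ODDS_CLAMP,
)

__all__ = [
    "GeneratorConfig",
    "default_model_spec",
    "demo_mapping_table",
    "generate_cohort",
    "generate_exclusion_fixture",
    "distort_predictions",
]


# ---------------------------------------------------------------------------
# Demo diagnosis mapping and true risk model
# ---------------------------------------------------------------------------

def demo_mapping_table() -> MappingTable:
    """Small bundled source-diagnosis mapping exercising every tier depth."""
    H = HierarchicalCode
    entries = {
        "SICS_PNEUMONIA": H("nonsurgical", "respiratory", "lung", "infection", "pneumonia"),
        "SICS_COPD": H("nonsurgical", "respiratory", "lung", "obstruction", "copd"),
        "SICS_ASTHMA": H("nonsurgical", "respiratory", "lung", "obstruction", "asthma"),
        "SICS_MI": H("nonsurgical", "cardiovascular", "heart", "ischaemia", "myocardial_infarction"),
        "SICS_CARDIAC_ARREST": H("nonsurgical", "cardiovascular", "heart", "arrest"),
        "SICS_GI_BLEED": H("nonsurgical", "gastrointestinal", "upper_gi", "haemorrhage"),
        "SICS_GI_PERF": H("surgical", "gastrointestinal", "bowel", "perforation"),
        "SICS_HEAD_INJURY": H("nonsurgical", "neurological", "brain", "trauma"),
        "SICS_STROKE": H("nonsurgical", "neurological", "brain"),
        "SICS_RENAL_FAILURE": H("nonsurgical", "renal"),
        "SICS_SEPSIS": H("nonsurgical", "cardiovascular", "systemic", "infection", "septic_shock"),
        "SICS_AAA_REPAIR": H("surgical", "cardiovascular", "aorta", "aneurysm"),
        # tokens the mapper could not place in the hierarchy
        "SICS_MISC_A": H(),
        "SICS_MISC_B": H(),
    }
    return MappingTable(entries=entries, provenance="bundled synthetic demo mapping")


#: mapped tokens of the demo table with sampling weights for the generator
_DIAG_TOKENS = (
    ("SICS_PNEUMONIA", 0.16),
    ("SICS_COPD", 0.07),
    ("SICS_ASTHMA", 0.03),
    ("SICS_MI", 0.10),
    ("SICS_CARDIAC_ARREST", 0.06),
    ("SICS_GI_BLEED", 0.09),
    ("SICS_GI_PERF", 0.10),
    ("SICS_HEAD_INJURY", 0.06),
    ("SICS_STROKE", 0.05),
    ("SICS_RENAL_FAILURE", 0.08),
    ("SICS_SEPSIS", 0.14),
    ("SICS_AAA_REPAIR", 0.06),
)

_SYSTEM_WEIGHTS = {
    "respiratory": 0.25,
    "cardiovascular": 0.10,
    "gastrointestinal": 0.05,
    "neurological": 0.35,
    "renal": 0.15,
}

_SYSTEM_SCORE_INTERACTION = {
    "respiratory": -0.003,
    "cardiovascular": 0.004,
    "gastrointestinal": 0.000,
    "neurological": 0.006,
    "renal": 0.002,
}


#: competitor log-odds noise SD emulating the published discrimination gap
#: (roughly 0.04 in c index at the default case mix)
COMPETITOR_NOISE_SD = 1.0


def default_model_spec(intercept: float = -6.15) -> ModelSpec:
    """Bundled synthetic demonstration risk model (death log-odds scale).

    A stand-in exercising the engine's full term vocabulary — continuous
    physiology score and age, categorical admission urgency, CPR and
    diagnostic body system, and a score-by-system interaction.  The
    coefficients are this package's own and deliberately not those of any
    published model; the intercept is set so the default case mix yields a
    mean predicted risk near 0.30 with the published spread.
    """
    return ModelSpec(
        name="synthetic_true_model",
        intercept=intercept,
        terms=(
            ContinuousTerm("physiology_score", 0.17),
            ContinuousTerm("age", 0.028),
            CategoricalTerm(
                "surgical_status",
                (("elective_scheduled", -1.1), ("emergency_urgent", -0.35)),
                reference="nonsurgical",
            ),
            CategoricalTerm("cpr_24h", (("True", 0.6),), reference="False"),
            CategoricalTerm(
                "diagnosis_system", tuple(_SYSTEM_WEIGHTS.items()), reference="trauma"
            ),
            InteractionTerm(
                "physiology_score",
                "diagnosis_system",
                tuple(_SYSTEM_SCORE_INTERACTION.items()),
                reference="trauma",
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    Marginal targets follow the published case-mix summary; the competitor
    distortion (c, d) is the inversion of the published legacy-model Cox
    calibration pattern (intercept -0.26, slope 0.91 on the survival
    log-odds scale), and ``noise_sd`` adds competitor-only information loss.
    """

    n: int = 23269
    seed: Optional[int] = None
    year_weights: Tuple[float, float, float] = (7396 / 23269, 7994 / 23269, 7879 / 23269)
    age_mean: float = 57.5
    age_sd: float = 18.0
    age_bounds: Tuple[float, float] = (16.0, 100.0)
    male_frac: float = 13058 / 23269
    surgical_fracs: Tuple[float, float, float] = (2438 / 23242, 5196 / 23242, 15608 / 23242)
    score_mean: float = 19.6
    score_sd: float = 9.5
    true_model: Optional[ModelSpec] = None
    distortion: Tuple[float, float] = (0.26 / 0.91, 1.0 / 0.91)  # (c, d)
    noise_sd: float = 0.0
    exclusion_fracs: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        for name, group in (
            ("year_weights", self.year_weights),
            ("surgical_fracs", self.surgical_fracs),
        ):
            if any(not 0 <= w <= 1 for w in group) or not np.isclose(sum(group), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be proportions summing to 1")
        if not 0 <= self.male_frac <= 1:
            raise ValueError("male_frac must be in [0, 1]")
        if self.distortion[1] == 0:
            raise ValueError("distortion slope d must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["true_model"] = json.loads((self.true_model or default_model_spec()).to_json())
        text = json.dumps(doc, indent=1, default=list)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


#: published exclusion-category proportions and mortality among all admissions
TABLE1_IMPACT_FRACS: Dict[str, Tuple[float, float]] = {
    "excluded_from_apache": (445 / 29626, 290 / 407),
    "low_risk": (2305 / 29626, 174 / 2291),
    "other_team": (88 / 29626, 35 / 88),
    "unspecified": (761 / 29626, 232 / 743),
}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def distort_predictions(
    preds: PredictionSet,
    c: float,
    d: float,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    name: str = "synthetic_competitor",
) -> PredictionSet:
    """Derive a competitor prediction set from a reference one.

    On the *survival* log-odds scale: optional additive Gaussian noise
    (information loss) followed by the linear miscalibration
    log-odds' = c + d * log-odds.  With (c, d) = (0, 1) and no noise the
    result carries identical risks.
    """
    surv_lo = -preds.log_odds
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        surv_lo = surv_lo + rng.normal(0.0, noise_sd, size=len(preds))
    surv_lo = np.clip(c + d * surv_lo, -LOG_ODDS_CLAMP, LOG_ODDS_CLAMP)
    death_lo = -surv_lo
    return PredictionSet(name, preds.admission_ids.copy(), death_lo, expit(death_lo),
                         preds.outcome.copy())


def _assign_impact_categories(
    records: pd.DataFrame,
    outcome: np.ndarray,
    fracs: Dict[str, Tuple[float, float]],
    rng: np.random.Generator,
) -> pd.Series:
    """Label records with exclusion-taxonomy categories matching target
    prevalence and per-category mortality (deaths sampled preferentially)."""
    n = len(records)
    labels = np.array([None] * n, dtype=object)
    free = np.ones(n, dtype=bool)
    for cat, (prop, mort) in fracs.items():
        k = int(round(prop * n))
        k_dead = min(int(round(k * mort)), int((free & (outcome == 1)).sum()))
        k_surv = min(k - k_dead, int((free & (outcome == 0)).sum()))
        dead_pool = np.flatnonzero(free & (outcome == 1))
        surv_pool = np.flatnonzero(free & (outcome == 0))
        chosen = np.concatenate(
            [
                rng.choice(dead_pool, size=k_dead, replace=False),
                rng.choice(surv_pool, size=k_surv, replace=False),
            ]
        )
        labels[chosen] = cat
        free[chosen] = False
    return pd.Series(labels, index=records.index, dtype=object)


def generate_cohort(
    cfg: Optional[GeneratorConfig] = None,
) -> Tuple[pd.DataFrame, PredictionSet, PredictionSet]:
    """Generate (records, preds_true, preds_distorted), reproducible from seed.

    ``preds_true`` are the true-model risks, well-calibrated by construction
    because the outcomes are drawn from them; ``preds_distorted`` applies
    the configured noise and (c, d) miscalibration.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    spec = cfg.true_model or default_model_spec()

    years = rng.choice([2007, 2008, 2009], size=n, p=np.asarray(cfg.year_weights))
    a, b = (
        (cfg.age_bounds[0] - cfg.age_mean) / cfg.age_sd,
        (cfg.age_bounds[1] - cfg.age_mean) / cfg.age_sd,
    )
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < cfg.male_frac, "male", "female")
    surgical = rng.choice(
        ["elective_scheduled", "emergency_urgent", "nonsurgical"],
        size=n,
        p=np.asarray(cfg.surgical_fracs),
    )
    # right-skewed integer physiology score (gamma matched to mean/SD, rounded)
    shape = (cfg.score_mean / cfg.score_sd) ** 2
    scale = cfg.score_sd**2 / cfg.score_mean
    score = np.clip(np.rint(rng.gamma(shape, scale, size=n)), 0, 100).astype(int)

    tokens, probs = zip(*_DIAG_TOKENS)
    diag = rng.choice(tokens, size=n, p=np.asarray(probs) / sum(p for _, p in _DIAG_TOKENS))
    table = demo_mapping_table()
    system = np.array([table.lookup(t).system_tier or "trauma" for t in diag], dtype=object)

    cpr = rng.random(n) < 0.05
    location = rng.choice(
        ["theatre", "emergency_department", "general_ward", "imaging", "recovery",
         "other_hospital", "home"],
        size=n,
        p=[0.32, 0.30, 0.22, 0.04, 0.05, 0.05, 0.02],
    )
    version = np.where(years == 2007, "v0", "v203")
    prev = np.array([None] * n, dtype=object)
    transient = np.isin(location, ["imaging", "recovery"]) & (version == "v203")
    prev[transient] = rng.choice(
        ["emergency_department", "general_ward", "theatre"], size=int(transient.sum()),
        p=[0.5, 0.35, 0.15],
    )

    highest_sbp = np.clip(rng.normal(148, 22, n), 80, 260)
    paired_dbp = np.clip(0.52 * highest_sbp + rng.normal(0, 8, n), 30, highest_sbp)
    lowest_dbp = np.clip(rng.normal(48, 12, n), 20, 100)
    paired_sbp_at_lowest = np.clip(lowest_dbp + np.abs(rng.normal(42, 12, n)), lowest_dbp, 250)
    ph_at_lowest_pao2 = np.clip(rng.normal(7.33, 0.09, n), 6.8, 7.65)
    gcs_present = rng.random(n) < 0.62
    gcs = np.where(gcs_present, rng.integers(3, 16, size=n).astype(float), np.nan)

    records = pd.DataFrame(
        {
            "admission_id": np.array([f"A{i:06d}" for i in range(n)]),
            "unit_id": rng.choice([f"U{j:02d}" for j in range(24)], size=n),
            "year": years,
            "age": np.round(age, 1),
            "sex": sex,
            "surgical_status": surgical,
            "location_prior": location,
            "previous_location": prev,
            "dataset_version": version,
            "cpr_24h": cpr,
            "highest_sbp": np.round(highest_sbp, 0),
            "paired_dbp_at_highest": np.round(paired_dbp, 0),
            "lowest_dbp": np.round(lowest_dbp, 0),
            "paired_sbp_at_lowest": np.round(paired_sbp_at_lowest, 0),
            "ph_at_lowest_pao2": np.round(ph_at_lowest_pao2, 2),
            "gcs_lowest": gcs,
            "physiology_score": score,
            "apache_score": np.nan,
            "diagnosis_code": diag,
            "diagnosis_system": system,
            "exclude_from_scoring": False,
            "exclude_reason": None,
            "is_readmission": False,
        }
    )
    model = LogisticRiskModel(spec)
    frame = records.assign(cpr_24h=records["cpr_24h"].astype(str))
    log_odds = model.predict_log_odds(frame)
    risk = expit(log_odds)
    outcome = (rng.random(n) < risk).astype(int)
    records["hospital_mortality"] = np.where(outcome == 1, "died", "survived")

    if cfg.exclusion_fracs is not None:
        records["impact_category"] = _assign_impact_categories(
            records, outcome, cfg.exclusion_fracs, rng
        )

    preds_true = PredictionSet(spec.name, records["admission_id"].to_numpy(),
                               log_odds, risk, outcome)
    c, d = cfg.distortion
    preds_distorted = distort_predictions(preds_true, c, d, noise_sd=cfg.noise_sd, rng=rng)
    return records, preds_true, preds_distorted


# ---------------------------------------------------------------------------
# Exclusion-cascade fixture
# ---------------------------------------------------------------------------

#: (sub-reason, flagged count, with-outcome count, deaths) — the flagged-
#: admission taxonomy with its reported outcome summaries
_FLAG_REASONS = (
    ("death_within_4h", 231, 231, 231),
    ("missing_core_physiology", 103, 101, 33),
    ("age_under_16", 65, 30, 5),
    ("primary_burn_injury", 46, 45, 21),
    ("high_dependency_unit", 1707, 1694, 116),
    ("post_surgical_recovery", 598, 597, 58),
    ("awaiting_transfer", 45, 45, 22),
    ("under_another_team", 43, 43, 13),
    ("unit_decision_not_to_score", 369, 360, 118),
    ("other_unspecified", 298, 293, 87),
    ("reason_missing", 94, 90, 27),
)

#: clean-cohort structure per year: (year, n, deaths)
_CLEAN_YEARS = ((2007, 7396, 2296), (2008, 7994, 2342), (2009, 7879, 2269))

_UNMAPPABLE_TOKENS = tuple(f"SICS_UNMAPPABLE_{k:02d}" for k in range(19))


def generate_exclusion_fixture() -> Tuple[pd.DataFrame, MappingTable]:
    """Deterministic 29,626-record fixture reproducing the exclusion cascade.

    Composition: 3,599 flagged for exclusion from scoring (sub-reason counts
    and outcome summaries as published: 3,529 with a reported outcome, of
    whom 731 died); 1,324 readmissions; 173 missing hospital mortality; 869
    missing location prior (16) or diagnosis (864), overlapping by 11; 392
    with an unmappable diagnosis; and 23,269 clean records (6,907 deaths)
    split across 2007-2009.  Returns the records and the mapping table under
    which the cascade runs.
    """
    table = demo_mapping_table()
    mapped_tokens = [t for t, _ in _DIAG_TOKENS]
    rows = []
    counter = 0

    def base_row():
        nonlocal counter
        row = {
            "admission_id": f"F{counter:06d}",
            "unit_id": f"U{counter % 24:02d}",
            "year": 2007 + counter % 3,
            "age": 60.0,
            "sex": "male" if counter % 2 else "female",
            "surgical_status": "nonsurgical",
            "location_prior": "general_ward",
            "previous_location": None,
            "dataset_version": "v203",
            "cpr_24h": False,
            "highest_sbp": 150.0,
            "paired_dbp_at_highest": 80.0,
            "lowest_dbp": 50.0,
            "paired_sbp_at_lowest": 95.0,
            "ph_at_lowest_pao2": 7.33,
            "gcs_lowest": 14.0,
            "physiology_score": 20,
            "apache_score": np.nan,
            "diagnosis_code": mapped_tokens[counter % len(mapped_tokens)],
            "exclude_from_scoring": False,
            "exclude_reason": None,
            "is_readmission": False,
            "hospital_mortality": "survived",
        }
        counter += 1
        return row

    # 1. flagged records with sub-reason outcome structure
    for reason, n_flag, n_outcome, n_dead in _FLAG_REASONS:
        for i in range(n_flag):
            row = base_row()
            row["exclude_from_scoring"] = True
            row["exclude_reason"] = None if reason == "reason_missing" else reason
            if i < n_dead:
                row["hospital_mortality"] = "died"
            elif i < n_outcome:
                row["hospital_mortality"] = "survived"
            else:
                row["hospital_mortality"] = None
            if reason == "age_under_16":
                row["age"] = 10.0
            rows.append(row)

    # 2. readmissions within the same hospital stay
    for i in range(1324):
        row = base_row()
        row["is_readmission"] = True
        row["hospital_mortality"] = "died" if i % 4 == 0 else "survived"
        rows.append(row)

    # 3. missing hospital mortality
    for _ in range(173):
        row = base_row()
        row["hospital_mortality"] = None
        rows.append(row)

    # 4. missing location prior (16) / diagnosis (864), overlapping by 11
    for i in range(869):
        row = base_row()
        if i < 16:
            row["location_prior"] = None
        if i >= 5:  # records 5..15 miss both fields
            row["diagnosis_code"] = None
        rows.append(row)

    # 5. unmappable diagnosis tokens
    for i in range(392):
        row = base_row()
        row["diagnosis_code"] = _UNMAPPABLE_TOKENS[i % len(_UNMAPPABLE_TOKENS)]
        rows.append(row)

    # clean cohort: exact year / death structure
    for year, n_year, n_dead in _CLEAN_YEARS:
        for i in range(n_year):
            row = base_row()
            row["year"] = year
            row["hospital_mortality"] = "died" if i < n_dead else "survived"
            rows.append(row)

    records = pd.DataFrame(rows)
    assert len(records) == 29626
    return records, table
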