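"""Binarization of six vascular risk factors and the weighted composite score.

Each factor is coded 1 if present, 0 if absent.  The composite score is the
dot product of the six indicators with a per-factor weight table (unit
weights by default; relative-risk weights can be supplied as a YAML/JSON
file — they are configuration, not constants of this package).

Boundary semantics: glucose, blood pressure and cigarettes use ``>=`` at
their thresholds; obesity uses strict ``> 30 kg/m^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FACTORS",
    "UNIT_WEIGHTS",
    "VrfMeasures",
    "VrfProfile",
    "MissingIndicatorError",
    "binarize_vrfs",
    "composite_score",
    "score_cohort",
    "load_weights",
]

FACTORS = (
    "diabetes",
    "hypertension",
    "smoking",
    "depression",
    "low_education",
    "obesity",
)

UNIT_WEIGHTS: dict[str, float] = {f: 1.0 for f in FACTORS}

GLUCOSE_THRESHOLD_MG_DL = 200.0
SBP_THRESHOLD_MMHG = 140.0
DBP_THRESHOLD_MMHG = 90.0
CIGARETTES_THRESHOLD = 20.0
BMI_THRESHOLD_KG_M2 = 30.0  # strict >

# sanity ranges for continuous measures when present
_RANGES = {
    "glucose_mg_dl": (0.0, 1500.0),
    "sbp_mmHg": (60.0, 300.0),
    "dbp_mmHg": (30.0, 200.0),
    "cigarettes_per_day": (0.0, 200.0),
    "bmi_kg_m2": (8.0, 100.0),
}


class MissingIndicatorError(ValueError):
    """A factor indicator is missing under the 'strict' missing-data policy."""


@dataclass
class VrfMeasures:
    """Raw clinical inputs for the six factors; ``None`` marks a missing value."""

    diabetes_selfreport: bool | None = None
    antidiabetic_meds: bool | None = None
    glucose_mg_dl: float | None = None
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None
    antihypertensive_meds: bool | None = None
    cigarettes_per_day: float | None = None
    major_depression_dx: bool | None = None
    low_education_flag: bool | None = None
    bmi_kg_m2: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            val = getattr(self, name)
            if val is not None and not (lo <= float(val) <= hi):
                raise ValueError(f"{name}={val} outside physiologic range [{lo}, {hi}]")


@dataclass
class VrfProfile:
    """Six 0/1 indicators plus the weighted composite score."""

    indicators: dict[str, int]
    composite_score: float
    weight_table_id: str = "unit"


def _indicator(positive: bool, inputs: tuple) -> int | None:
    if positive:
        return 1
    if all(v is None for v in inputs):
        return None
    return 0


def binarize_vrfs(m: VrfMeasures) -> dict[str, int | None]:
    """Map raw measures to the six 0/1 indicators.

    A factor whose inputs are entirely missing yields ``None`` rather than a
    silent 0; downstream policy decides how that is handled.
    """
    diabetes = _indicator(
        bool(m.diabetes_selfreport)
        or bool(m.antidiabetic_meds)
        or (m.glucose_mg_dl is not None and m.glucose_mg_dl >= GLUCOSE_THRESHOLD_MG_DL),
        (m.diabetes_selfreport, m.antidiabetic_meds, m.glucose_mg_dl),
    )
    # "untreated" thresholds apply when not on antihypertensives; medicated
    # subjects are hypertensive regardless of readings.  A supra-threshold
    # reading qualifies even if medication status is unknown (either branch
    # of the OR would fire).
    untreated = not bool(m.antihypertensive_meds)
    hypertension = _indicator(
        bool(m.antihypertensive_meds)
        or (untreated and m.sbp_mmHg is not None and m.sbp_mmHg >= SBP_THRESHOLD_MMHG)
        or (untreated and m.dbp_mmHg is not None and m.dbp_mmHg >= DBP_THRESHOLD_MMHG),
        (m.antihypertensive_meds, m.sbp_mmHg, m.dbp_mmHg),
    )
    smoking = _indicator(
        m.cigarettes_per_day is not None and m.cigarettes_per_day >= CIGARETTES_THRESHOLD,
        (m.cigarettes_per_day,),
    )
    depression = _indicator(bool(m.major_depression_dx), (m.major_depression_dx,))
    low_education = _indicator(bool(m.low_education_flag), (m.low_education_flag,))
    obesity = _indicator(
        m.bmi_kg_m2 is not None and m.bmi_kg_m2 > BMI_THRESHOLD_KG_M2,
        (m.bmi_kg_m2,),
    )
    return {
        "diabetes": diabetes,
        "hypertension": hypertension,
        "smoking": smoking,
        "depression": depression,
        "low_education": low_education,
        "obesity": obesity,
    }


def composite_score(
    indicators: Mapping[str, int | None],
    weights: Mapping[str, float] | None = None,
    missing_policy: str = "strict",
) -> float:
    """Weighted sum of the six indicators.

    With unit weights the score equals the count of present factors.
    ``missing_policy``: "strict" raises on any missing indicator;
    "zero-impute" treats missing as absent with a logged warning.
    """
    weights = dict(UNIT_WEIGHTS if weights is None else weights)
    unknown = set(weights) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors in weight table: {sorted(unknown)}")
    missing_weights = set(FACTORS) - set(weights)
    if missing_weights:
        raise ValueError(f"weight table lacks factors: {sorted(missing_weights)}")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be positive")

    total = 0.0
    for factor in FACTORS:
        ind = indicators.get(factor)
        if ind is None:
            if missing_policy == "strict":
                raise MissingIndicatorError(f"indicator '{factor}' is missing")
            elif missing_policy == "zero-impute":
                logger.warning("indicator '%s' missing; imputed as 0", factor)
                ind = 0
            else:
                raise ValueError(f"unknown missing policy: {missing_policy!r}")
        if ind not in (0, 1):
            raise ValueError(f"indicator '{factor}' must be 0 or 1, got {ind!r}")
        total += weights[factor] * ind
    return total


def score_cohort(
    cohort: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    missing_policy: str = "strict",
    prefix: str = "vrf_",
    out_column: str = "vrf_score",
) -> pd.DataFrame:
    """Append the composite score to a cohort table with ``vrf_<factor>`` columns."""
    cols = [prefix + f for f in FACTORS]
    missing_cols = [c for c in cols if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks indicator columns: {missing_cols}")
    scored = cohort.copy()
    scores = []
    for _, row in cohort.iterrows():
        indicators = {
            f: (None if pd.isna(row[prefix + f]) else int(row[prefix + f])) for f in FACTORS
        }
        scores.append(composite_score(indicators, weights, missing_policy))
    scored[out_column] = scores
    return scored


def load_weights(path: str | Path) -> dict[str, float]:
    """Read a {factor: weight} table from YAML or JSON."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, dict):
        raise ValueError(f"weight table in {path} is not a mapping")
    return {str(k): float(v) for k, v in table.items()}
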