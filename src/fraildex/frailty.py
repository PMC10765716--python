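"""Frailty-index construction from a deficit codebook.

The frailty index (FI) of a person is the sum of their deficit scores
divided by the number of deficits with valid (non-missing) data, so it is
a proportion in [0, 1].  An FI is only defined when more than 80% of the
items have valid data (with 41 items: at least 34 valid); otherwise the
index is reported as undefined rather than imputed.  Persons are further
stratified as robust (FI < 0.10), pre-frail (0.10 <= FI <= 0.21) or frail
(FI > 0.21).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .codebook import DeficitSchema, DeficitSpec

__all__ = [
    "PersonRecord",
    "FIResult",
    "ScoringError",
    "VALIDITY_FRACTION",
    "ROBUST_CUTOFF",
    "FRAIL_CUTOFF",
    "CATEGORIES",
    "score_item",
    "bmi_band_score",
    "compute_fi",
    "categorize_fi",
    "min_deficits_for_threshold",
    "sensitivity_subset",
    "score_cohort",
]

#: More than this fraction of items must be valid for the FI to be defined
#: (strict inequality: "more than 80%").
VALIDITY_FRACTION = 0.80

#: FI strictly below this value -> robust.
ROBUST_CUTOFF = 0.10
#: FI strictly above this value -> frail; [ROBUST_CUTOFF, FRAIL_CUTOFF] -> pre-frail.
FRAIL_CUTOFF = 0.21

CATEGORIES = ("robust", "pre_frail", "frail")

_MISSING_STRINGS = {"", "na", "nan", "none", "null", "missing", "."}


class ScoringError(ValueError):
    """Raised for response values that are neither missing nor a known level."""


@dataclass
class PersonRecord:
    """Raw survey responses plus socio-demographics for one participant."""

    person_id: str
    responses: Mapping[str, object]
    age: float
    sex: str  # "male" | "female"
    education: str  # "low" | "medium" | "high"
    living_alone: str  # "no" | "yes"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"person {self.person_id}: age must be positive")


@dataclass
class FIResult:
    """Frailty index for one person, with per-item audit trail."""

    person_id: str
    fi: Optional[float]
    n_valid: int
    n_items: int
    item_scores: Mapping[str, Optional[float]]
    category: Optional[str]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.fi is not None


def bmi_band_score(bmi: float) -> float:
    """Score a numeric body-mass index into deficit bands.

    Normal weight (18.5 <= BMI < 25) scores 0, overweight
    (25 <= BMI <= 30) scores 0.5, underweight (BMI < 18.5) or obesity
    (BMI > 30) scores 1.  Band edges are inclusive as written: BMI of
    exactly 25 or 30 is overweight, exactly 18.5 is normal.
    """
    if not (bmi > 0 and math.isfinite(bmi)):
        raise ScoringError(f"BMI must be a positive finite number, got {bmi}")
    if 18.5 <= bmi < 25.0:
        return 0.0
    if 25.0 <= bmi <= 30.0:
        return 0.5
    return 1.0


def score_item(spec: DeficitSpec, raw_response: object) -> Optional[float]:
    """Map one raw response to its deficit score, or None when missing.

    Unknown response codes raise :class:`ScoringError` rather than being
    treated as missing: silently dropping them would corrupt the >80%
    validity rule.  For the BMI item a numeric response is binned with
    :func:`bmi_band_score`; a band code is also accepted.
    """
    if raw_response is None or (
        isinstance(raw_response, float) and math.isnan(raw_response)
    ):
        return None
    if spec.kind == "bmi_band" and isinstance(raw_response, (int, float, np.floating)):
        return bmi_band_score(float(raw_response))
    key = str(raw_response).strip()
    # level codes win over missing-value sentinels ("none" is a valid level)
    if key in spec.level_map:
        return float(spec.level_map[key])
    if key.lower() in _MISSING_STRINGS:
        return None
    if spec.kind == "bmi_band":
        # numeric BMI arriving as a string, e.g. from CSV
        try:
            return bmi_band_score(float(key))
        except (TypeError, ValueError):
            pass
    raise ScoringError(
        f"item {spec.item_id!r}: unknown response {raw_response!r}; "
        f"expected one of {list(spec.level_map)} or missing"
    )


def categorize_fi(fi: float) -> str:
    """Assign the frailty category for an FI value.

    Robust strictly below 0.10, frail strictly above 0.21, pre-frail on
    the closed interval in between (so 9 deficits of 41, FI ~ 0.2195, is
    frail while FI exactly 0.21 is pre-frail).
    """
    if not (0.0 <= fi <= 1.0):
        raise ValueError(f"FI must lie in [0, 1], got {fi}")
    if fi < ROBUST_CUTOFF:
        return "robust"
    if fi <= FRAIL_CUTOFF:
        return "pre_frail"
    return "frail"


def min_deficits_for_threshold(threshold: float, n_items: int) -> int:
    """Smallest integer deficit count d with d / n_items > threshold.

    With the frail cut-off 0.21 and 41 items this is 9: a person needs 9
    or more unit-weight deficits to be classified frail.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    for d in range(1, n_items + 1):
        if d / n_items > threshold:
            return d
    raise ValueError(f"no deficit count of {n_items} exceeds {threshold}")


def compute_fi(
    record: PersonRecord | Mapping[str, object],
    schema: DeficitSchema,
) -> FIResult:
    """Compute the frailty index for one person.

    The FI is the sum of non-missing item scores divided by the count of
    non-missing items.  When 80% or fewer items are valid the FI (and its
    category) are undefined and ``reason`` explains why; an empty record
    yields an undefined FI rather than an error.
    """
    if isinstance(record, PersonRecord):
        person_id, responses = record.person_id, record.responses
    else:
        responses = record
        person_id = str(responses.get("person_id", ""))
    scores: dict[str, Optional[float]] = {}
    for spec in schema:
        scores[spec.item_id] = score_item(spec, responses.get(spec.item_id))
    valid = [s for s in scores.values() if s is not None]
    n_valid, n_items = len(valid), len(schema)
    if n_valid / n_items <= VALIDITY_FRACTION:
        return FIResult(
            person_id=person_id,
            fi=None,
            n_valid=n_valid,
            n_items=n_items,
            item_scores=scores,
            category=None,
            reason=(
                f"only {n_valid}/{n_items} items valid; more than "
                f"{VALIDITY_FRACTION:.0%} required"
            ),
        )
    fi = float(sum(valid) / n_valid)
    return FIResult(
        person_id=person_id,
        fi=fi,
        n_valid=n_valid,
        n_items=n_items,
        item_scores=scores,
        category=categorize_fi(fi),
    )


def sensitivity_subset(schema: DeficitSchema) -> DeficitSchema:
    """Schema without the cardiovascular diagnosis/risk-factor items.

    With the default 41-item codebook this drops myocardial infarction,
    coronary heart disease, hypertension and stroke, leaving 37 items; the
    >80% validity rule then applies to the reduced count.
    """
    return schema.without_cvd_items()


def score_cohort(
    cohort: pd.DataFrame,
    schema: DeficitSchema,
    *,
    id_col: str = "person_id",
) -> pd.DataFrame:
    """Vectorized frailty-index scoring of a cohort table.

    Parameters
    ----------
    cohort
        One row per person; item columns named by ``item_id``, missing
        cells empty/NA.
    schema
        The deficit codebook to score against.

    Returns
    -------
    DataFrame with columns ``person_id``, ``fi``, ``n_valid``,
    ``category`` (category is NA where the FI is undefined).
    """
    missing_cols = [i for i in schema.item_ids if i not in cohort.columns]
    if missing_cols:
        raise KeyError(
            f"cohort table is missing {len(missing_cols)} item column(s): "
            f"{missing_cols}"
        )
    score_mat = np.full((len(cohort), len(schema)), np.nan)
    for j, spec in enumerate(schema):
        col = cohort[spec.item_id]
        raw = col.astype("string").str.strip()
        mapped = raw.map({str(k): v for k, v in spec.level_map.items()})
        # level codes win over missing-value sentinels ("none" is a valid level)
        is_missing = (
            col.isna() | raw.str.lower().isin(_MISSING_STRINGS)
        ) & mapped.isna()
        if spec.kind == "bmi_band":
            numeric = pd.to_numeric(raw, errors="coerce")
            num_scores = numeric.map(
                lambda b: bmi_band_score(b) if pd.notna(b) else np.nan
            )
            mapped = num_scores.where(numeric.notna(), mapped)
        bad = (~is_missing) & mapped.isna()
        if bad.any():
            examples = sorted(set(raw[bad].dropna()))[:5]
            raise ScoringError(
                f"item {spec.item_id!r}: {int(bad.sum())} unknown response(s), "
                f"e.g. {examples}"
            )
        score_mat[:, j] = mapped.astype(float).to_numpy()
    n_valid = (~np.isnan(score_mat)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(score_mat, axis=1) / n_valid
    defined = n_valid / len(schema) > VALIDITY_FRACTION
    fi = np.where(defined, fi, np.nan)
    category = pd.Series(pd.NA, index=cohort.index, dtype="string")
    category[defined & (fi < ROBUST_CUTOFF)] = "robust"
    category[defined & (fi >= ROBUST_CUTOFF) & (fi <= FRAIL_CUTOFF)] = "pre_frail"
    category[defined & (fi > FRAIL_CUTOFF)] = "frail"
    out = pd.DataFrame(
        {
            "person_id": cohort[id_col].to_numpy()
            if id_col in cohort.columns
            else np.arange(len(cohort)),
            "fi": fi,
            "n_valid": n_valid,
            "category": category,
        }
    )
    return out
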