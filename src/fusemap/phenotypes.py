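"""Pubertal Development Scale (PDS) scoring and psychopathology proxies.

Sex-specific 4-point PDS items are averaged into PDS_mean, differenced across
visits into delta-PDS, and summed into pubertal categories (prepubertal to
postpubertal). Psychopathology severity is proxied by the count of consensus
diagnoses; a dimensional total (e.g. CBCL) is passed through as provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MALE_ITEMS",
    "FEMALE_ITEMS",
    "CATEGORY_ORDER",
    "PubertalSummary",
    "pds_mean",
    "pds_delta",
    "pubertal_category",
    "diagnosis_sum",
    "score_phenotype_table",
    "MissingItemError",
]

# 4-point ordinal items administered per sex; females additionally report
# menarche as a binary item, recoded {no: 1, yes: 4} for the mean.
MALE_ITEMS = ("growth_spurt", "body_hair", "skin_change", "facial_hair", "voice_deepening")
FEMALE_ITEMS = ("growth_spurt", "body_hair", "skin_change", "breast_development")
MENARCHE_RECODE = {0: 1.0, 1: 4.0}

CATEGORY_ORDER = ("prepubertal", "early", "mid", "late", "post")


class MissingItemError(ValueError):
    """A required sex-specific item is missing or marked 'don't know'."""


@dataclass
class PubertalSummary:
    pds_mean: float
    category: str | None = None
    reporter: str = "caregiver"


def _valid_item(v) -> float:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        raise MissingItemError("missing item response")
    v = float(v)
    if not (1 <= v <= 4):
        raise ValueError(f"item response {v} outside the 1-4 scale")
    return v


def pds_mean(items: dict, sex: str, menarche=None) -> float:
    """Average PDS score over the sex-specific item set (range [1, 4]).

    Missing items raise MissingItemError; table-level scoring excludes such
    subjects listwise.
    """
    sex = str(sex).lower()
    if sex == "male":
        vals = [_valid_item(items.get(k)) for k in MALE_ITEMS]
    elif sex == "female":
        vals = [_valid_item(items.get(k)) for k in FEMALE_ITEMS]
        if menarche is None or (isinstance(menarche, float) and math.isnan(menarche)):
            raise MissingItemError("missing menarche response")
        vals.append(MENARCHE_RECODE[int(menarche)])
    else:
        raise ValueError(f"unknown sex '{sex}'")
    return float(np.mean(vals))


def pds_delta(baseline: PubertalSummary, followup: PubertalSummary) -> float:
    """Follow-up minus baseline PDS_mean, valid only within one reporter."""
    if baseline.reporter != followup.reporter:
        raise ValueError("delta PDS requires the same reporter at both visits")
    return followup.pds_mean - baseline.pds_mean


def pubertal_category(items: dict, sex: str, menarche=None) -> str:
    """Pubertal category from sex-specific item sums.

    Males sum pubic/body hair, facial hair and voice deepening (range 3-12);
    females sum body hair and breast development (range 2-8) and incorporate
    menarche. Boundaries follow the standard Petersen/Crockett-derived
    conversion used with the PDS.
    """
    sex = str(sex).lower()
    if sex == "male":
        vals = [int(_valid_item(items.get(k))) for k in ("body_hair", "facial_hair", "voice_deepening")]
        total = sum(vals)
        if total == 3:
            return "prepubertal"
        if total <= 5 and max(vals) < 3:
            return "early"
        if total <= 8 and max(vals) < 4:
            return "mid"
        if total <= 11:
            return "late"
        return "post"
    if sex == "female":
        vals = [int(_valid_item(items.get(k))) for k in ("body_hair", "breast_development")]
        total = sum(vals)
        if menarche is None or (isinstance(menarche, float) and math.isnan(menarche)):
            raise MissingItemError("missing menarche response")
        if int(menarche):
            return "post" if total == 8 else "late"
        if total == 2:
            return "prepubertal"
        if total == 3:
            return "early"
        return "mid"
    raise ValueError(f"unknown sex '{sex}'")


def diagnosis_sum(diagnoses) -> int:
    """Count of consensus diagnoses (psychopathology severity proxy)."""
    return len(list(diagnoses))


def _item_columns(sex: str):
    return MALE_ITEMS if sex == "male" else FEMALE_ITEMS


def score_phenotype_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add pds_mean and pubertal category columns to a phenotype table.

    Expects per-item columns named pds_<item> plus 'sex' and, for females,
    'menarche'. Subjects with missing items get NaN (listwise per score).
    """
    out = pheno.copy()
    means, cats = [], []
    for _, row in out.iterrows():
        sex = str(row["sex"]).lower()
        items = {k: row.get(f"pds_{k}") for k in _item_columns(sex)}
        men = row.get("menarche") if sex == "female" else None
        try:
            means.append(pds_mean(items, sex, men))
        except MissingItemError:
            means.append(np.nan)
        try:
            cats.append(pubertal_category(items, sex, men))
        except (MissingItemError, ValueError):
            cats.append(None)
    out["pds_mean"] = means
    out["pds_category"] = cats
    return out
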