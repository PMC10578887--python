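"""Eight-group trichotomy classification and prevalence reporting.

With the three normalized axes (cognition, AD factor, vascular factor) each
anchored so 0.5 separates factor-negative from factor-positive, every
subject falls in one octant of the unit cube. The sign triple
(Cog, ADF, VDF), with "+" meaning strictly above the threshold, names the
subgroup:

====== ===== ===== ===== =================================================
label   Cog   ADF   VDF  meaning
====== ===== ===== ===== =================================================
bMX      +     +     +   biological mixed dementia
bAD      +     +     −   biological Alzheimer's disease
bVD      +     −     +   biological vascular disease (SIVD-like)
bCL      +     −     −   cognitively low, no AD or VD factors
bCN_MX   −     +     +   cognitively normal, AD and VD factors (preclinical MX)
bCN_AD   −     +     −   cognitively normal, AD factors (preclinical AD)
bCN_VD   −     −     +   cognitively normal, VD factors (preclinical VD)
bCN      −     −     −   cognitively normal, no AD or VD factors
====== ===== ===== ===== =================================================

A score exactly at the threshold counts as negative (the cognition split is
"Cog ≤ 0.5" vs "Cog > 0.5").
"""

from __future__ import annotations

import decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrichotomyLabel",
    "classify_subject",
    "classify_table",
    "group_prevalence",
    "aggregate_membership",
    "crosstab_clinical",
    "CLINICAL_CATEGORIES",
]

CLINICAL_CATEGORIES = ("aCN", "aMCI", "aAD")


class TrichotomyLabel(str, Enum):
    """The eight biologically defined subgroups (b = biological)."""

    bMX = "bMX"
    bAD = "bAD"
    bVD = "bVD"
    bCL = "bCL"
    bCN_MX = "bCN_MX"
    bCN_AD = "bCN_AD"
    bCN_VD = "bCN_VD"
    bCN = "bCN"

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]

    @property
    def sign_triple(self) -> tuple:
        """(cog_positive, adf_positive, vdf_positive) for this subgroup."""
        return _SIGNS_BY_LABEL[self]


_SIGN_TO_LABEL = {
    (True, True, True): TrichotomyLabel.bMX,
    (True, True, False): TrichotomyLabel.bAD,
    (True, False, True): TrichotomyLabel.bVD,
    (True, False, False): TrichotomyLabel.bCL,
    (False, True, True): TrichotomyLabel.bCN_MX,
    (False, True, False): TrichotomyLabel.bCN_AD,
    (False, False, True): TrichotomyLabel.bCN_VD,
    (False, False, False): TrichotomyLabel.bCN,
}
_SIGNS_BY_LABEL = {v: k for k, v in _SIGN_TO_LABEL.items()}

_DESCRIPTIONS = {
    TrichotomyLabel.bMX: "biological mixed dementia",
    TrichotomyLabel.bAD: "biological Alzheimer's disease",
    TrichotomyLabel.bVD: "biological vascular disease (SIVD)",
    TrichotomyLabel.bCL: "cognitively low performers, no AD or VD factors",
    TrichotomyLabel.bCN_MX: "preclinical mixed (normal cognition, AD and VD factors)",
    TrichotomyLabel.bCN_AD: "preclinical AD (normal cognition, AD factors)",
    TrichotomyLabel.bCN_VD: "preclinical VD (normal cognition, VD factors)",
    TrichotomyLabel.bCN: "cognitively normal, no AD or VD factors",
}

LABEL_ORDER = (
    TrichotomyLabel.bMX,
    TrichotomyLabel.bAD,
    TrichotomyLabel.bVD,
    TrichotomyLabel.bCL,
    TrichotomyLabel.bCN_MX,
    TrichotomyLabel.bCN_AD,
    TrichotomyLabel.bCN_VD,
    TrichotomyLabel.bCN,
)


def _check_score(name: str, value: float) -> float:
    v = float(value)
    if not (0.0 < v < 1.0):
        raise ValueError(f"{name} must lie strictly inside (0,1), got {v!r}")
    return v


def classify_subject(
    cog_norm: float,
    adf_norm: float,
    vdf_norm: float,
    threshold: float = 0.5,
) -> TrichotomyLabel:
    """Assign the trichotomy subgroup from three normalized scores.

    An axis is positive iff its score is strictly greater than ``threshold``
    (a score exactly at the threshold is negative).
    """
    cog = _check_score("cog_norm", cog_norm)
    adf = _check_score("adf_norm", adf_norm)
    vdf = _check_score("vdf_norm", vdf_norm)
    return _SIGN_TO_LABEL[(cog > threshold, adf > threshold, vdf > threshold)]


def classify_table(
    cog_norm, adf_norm, vdf_norm, threshold: float = 0.5
) -> pd.Series:
    """Vectorized classification; returns a Series of label strings."""
    cog = np.asarray(cog_norm, dtype=float)
    adf = np.asarray(adf_norm, dtype=float)
    vdf = np.asarray(vdf_norm, dtype=float)
    out = [
        classify_subject(c, a, v, threshold).value
        for c, a, v in zip(cog, adf, vdf)
    ]
    return pd.Series(out, dtype="object")


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _as_label_values(labels: Iterable) -> list:
    return [TrichotomyLabel(l).value for l in labels]


def group_prevalence(labels: Iterable) -> pd.DataFrame:
    """Per-group count and percentage (half-up, one decimal) over a cohort.

    Returns a DataFrame indexed by the eight labels in canonical order with
    columns ``n`` and ``percent``; counts sum to the cohort size.
    """
    vals = _as_label_values(labels)
    if len(vals) == 0:
        raise ValueError("empty label vector")
    n = len(vals)
    counts = pd.Series(vals).value_counts()
    rows = []
    for lab in LABEL_ORDER:
        c = int(counts.get(lab.value, 0))
        rows.append({"group": lab.value, "n": c, "percent": _round_half_up(100.0 * c / n)})
    return pd.DataFrame(rows).set_index("group")


def aggregate_membership(
    labels: Iterable,
    subset: Iterable,
    clinical_labels: Optional[Sequence] = None,
    within: Optional[str] = None,
) -> tuple:
    """Count subjects with a label in ``subset``, optionally within a
    clinical stratum.

    Returns ``(numerator, denominator, percent)`` with the percentage
    rounded half-up to one decimal, matching prevalence statements such as
    "107 of 186 aMCI subjects (57.5%) had AD factors".
    """
    vals = np.asarray(_as_label_values(labels), dtype=object)
    sub = {TrichotomyLabel(s).value for s in subset}
    if not sub:
        raise ValueError("subset must be non-empty")
    if within is not None:
        if clinical_labels is None:
            raise ValueError("clinical_labels required when 'within' is given")
        clin = np.asarray(list(clinical_labels), dtype=object)
        if clin.shape != vals.shape:
            raise ValueError("labels and clinical_labels must align")
        mask = clin == within
        if not mask.any():
            raise ValueError(f"empty clinical stratum: {within!r}")
        vals = vals[mask]
    denom = int(vals.size)
    num = int(np.sum(np.isin(vals, list(sub))))
    return num, denom, _round_half_up(100.0 * num / denom)


def crosstab_clinical(labels: Iterable, clinical_labels: Iterable) -> pd.DataFrame:
    """8×3 contingency table of trichotomy subgroup vs clinical diagnosis.

    Rows are the eight subgroups in canonical order, columns the clinical
    categories (aCN, aMCI, aAD); a margin row/column ("All") is included.
    """
    vals = _as_label_values(labels)
    clin = list(clinical_labels)
    if len(vals) != len(clin):
        raise ValueError("labels and clinical_labels must align")
    unknown = set(clin) - set(CLINICAL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown clinical categories: {sorted(unknown)}")
    tab = pd.crosstab(
        pd.Categorical(vals, categories=[l.value for l in LABEL_ORDER]),
        pd.Categorical(clin, categories=list(CLINICAL_CATEGORIES)),
        dropna=False,
        margins=True,
        margins_name="All",
    )
    tab.index.name = "group"
    tab.columns.name = "clinical"
    return tab
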