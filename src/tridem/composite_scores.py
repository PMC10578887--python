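"""Raw composite biomarker axes and their derivation by linear discriminant analysis.

A composite axis is a linear rule over transformed biomarkers::

    CS_raw = sum_j  w_j * t_j(x_j)  +  b

together with a cutoff ``cth`` on the raw scale. Scores above ``cth`` are
disease-positive (or, for the cognition axis, cognitively low). Three axes
ship as immutable presets (the ``ADNI-2023`` set):

* ``VDF`` — vascular disease factor from white-matter mean free water (mFW)
  and peak width of skeletonized mean diffusivity (PSMD), derived by LDA on
  a vascular-enriched cohort; cth = 0.
* ``Cog`` — cognition from the composite memory (ADNI_MEM) and executive
  (ADNI_EF) scores, derived by LDA separating cognitively normal from
  impaired subjects; larger = worse cognition; cth = 0.
* ``ADF`` — Alzheimer's disease factor, log10(pTau / Aβ42), with the
  CSF-vs-PET concordance cutoff log10(0.022).

``fit_lda_axis`` reproduces how the LDA-derived presets were constructed:
Fisher two-class LDA with pooled within-class covariance and equal priors,
the weight vector rescaled to unit Euclidean norm and oriented so the
patient class projects positive, and the intercept chosen so the midpoint
of the projected class means sits at raw score 0 (hence cth = 0).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTransform",
    "LinearCompositeDefinition",
    "PRESET_AXES",
    "get_preset_axis",
    "compute_vdf_raw",
    "compute_cog_raw",
    "compute_adf_raw",
    "fit_lda_axis",
    "classification_accuracy",
    "loocv_accuracy",
    "DegenerateSeparationError",
]


class DegenerateSeparationError(ValueError):
    """Raised when the two LDA classes have identical means."""


@dataclass(frozen=True)
class FeatureTransform:
    """A per-feature input transform applied before the linear combination.

    ``kind`` is ``"identity"`` or ``"log10"``; ``scale`` multiplies the raw
    input before the log (e.g. PSMD in mm²/s is scaled by 1e4 so the log
    argument is of order 1). Keeping the transform inside the axis
    definition prevents silent unit errors by callers.
    """

    kind: str = "identity"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "log10"):
            raise ValueError(f"unknown transform kind: {self.kind!r}")
        if not (self.scale > 0):
            raise ValueError("transform scale must be positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x * self.scale
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = x * self.scale
        if np.any(np.asarray(scaled) <= 0):
            raise ValueError(
                f"log10 transform requires positive input (scale={self.scale:g})"
            )
        return np.log10(scaled)


@dataclass(frozen=True)
class LinearCompositeDefinition:
    """A named linear raw-score rule with its cutoff.

    Attributes
    ----------
    name : str
        Axis name (``ADF``, ``VDF``, ``Cog`` or user-defined).
    features : tuple of (str, FeatureTransform)
        Ordered source columns and their input transforms.
    coefficients : tuple of float
        One weight per feature. LDA-derived axes have a unit-Euclidean-norm
        weight vector (within 1e-3).
    intercept : float
    cth : float
        Cutoff on the raw scale; raw score above ``cth`` is factor-positive.
    provenance : str
        Free-text origin note (preset set name, or fit metadata).
    """

    name: str
    features: tuple
    coefficients: tuple
    intercept: float
    cth: float
    provenance: str = "user"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients must align")

    @property
    def feature_names(self) -> tuple:
        return tuple(name for name, _ in self.features)

    def coefficient_norm(self) -> float:
        return float(np.linalg.norm(self.coefficients))

    def transform_features(self, table: pd.DataFrame) -> np.ndarray:
        """Apply each feature's input transform; returns an (n, p) array."""
        cols = []
        for (col, tf) in self.features:
            if col not in table.columns:
                raise KeyError(f"missing column: {col}")
            cols.append(tf(table[col].to_numpy(dtype=float)))
        return np.column_stack(cols)

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Raw composite score per row; NaN where any input is missing."""
        X = self.transform_features(table)
        return X @ np.asarray(self.coefficients, dtype=float) + self.intercept

    def score_values(self, *values: float) -> float:
        """Score a single subject from positional feature values."""
        row = pd.DataFrame([dict(zip(self.feature_names, values))])
        return float(self.score(row)[0])

    # -- plain-text (YAML) serialization; round-trips decimal strings exactly
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": [
                {"field": col, "transform": tf.kind, "scale": repr(tf.scale)}
                for col, tf in self.features
            ],
            "coefficients": [repr(c) for c in self.coefficients],
            "intercept": repr(self.intercept),
            "cth": repr(self.cth),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearCompositeDefinition":
        feats = tuple(
            (f["field"], FeatureTransform(f["transform"], float(f.get("scale", 1.0))))
            for f in d["features"]
        )
        return cls(
            name=d["name"],
            features=feats,
            coefficients=tuple(float(c) for c in d["coefficients"]),
            intercept=float(d["intercept"]),
            cth=float(d["cth"]),
            provenance=d.get("provenance", "user"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LinearCompositeDefinition":
        return cls.from_dict(yaml.safe_load(text))


def _preset(name, features, coefficients, intercept, cth):
    return LinearCompositeDefinition(
        name=name,
        features=features,
        coefficients=coefficients,
        intercept=intercept,
        cth=cth,
        provenance="ADNI-2023",
    )


#: Published axis registry. Immutable; select by name.
PRESET_AXES: Mapping[str, LinearCompositeDefinition] = {
    "VDF": _preset(
        "VDF",
        (
            ("psmd", FeatureTransform("log10", 1e4)),
            ("mfw", FeatureTransform("log10", 1e2)),
        ),
        (0.135, 0.991),
        -1.474,
        0.0,
    ),
    "Cog": _preset(
        "Cog",
        (
            ("adni_ef", FeatureTransform("identity")),
            ("adni_mem", FeatureTransform("identity")),
        ),
        (-0.076, -0.997),
        0.519,
        0.0,
    ),
    "ADF": _preset(
        "ADF",
        (
            ("ptau", FeatureTransform("log10")),
            ("abeta42", FeatureTransform("log10")),
        ),
        (1.0, -1.0),
        0.0,
        math.log10(0.022),
    ),
}


def get_preset_axis(name: str) -> LinearCompositeDefinition:
    """Return a published preset axis by name (``ADF``, ``VDF``, ``Cog``)."""
    try:
        return PRESET_AXES[name]
    except KeyError:
        raise KeyError(
            f"unknown preset axis {name!r}; available: {sorted(PRESET_AXES)}"
        ) from None


def compute_vdf_raw(mfw, psmd):
    """Vascular disease factor raw score.

    VDF_raw = 0.135*log10(PSMD*1e4) + 0.991*log10(mFW*1e2) - 1.474, cth = 0.

    Parameters are the white-matter mean free water fraction (dimensionless,
    in (0,1)) and PSMD in mm²/s. Both must be positive.
    """
    mfw = np.asarray(mfw, dtype=float)
    psmd = np.asarray(psmd, dtype=float)
    if np.any(mfw <= 0) or np.any(psmd <= 0):
        raise ValueError("mfw and psmd must be positive (log10 undefined otherwise)")
    out = 0.135 * np.log10(psmd * 1e4) + 0.991 * np.log10(mfw * 1e2) - 1.474
    return out if out.ndim else float(out)


def compute_cog_raw(adni_mem, adni_ef):
    """Cognition raw score: -0.076*ADNI_EF - 0.997*ADNI_MEM + 0.519, cth = 0.

    Larger values mean worse cognition (both inputs enter negatively).
    """
    adni_mem = np.asarray(adni_mem, dtype=float)
    adni_ef = np.asarray(adni_ef, dtype=float)
    out = -0.076 * adni_ef - 0.997 * adni_mem + 0.519
    return out if out.ndim else float(out)


def compute_adf_raw(abeta42, ptau):
    """Alzheimer's disease factor raw score: log10(pTau / Aβ42).

    Inputs are CSF concentrations in pg/mL; the axis cutoff is
    log10(0.022) ≈ -1.66, the pTau/Aβ42 ratio concordant with amyloid-PET
    positivity.
    """
    abeta42 = np.asarray(abeta42, dtype=float)
    ptau = np.asarray(ptau, dtype=float)
    if np.any(abeta42 <= 0) or np.any(ptau <= 0):
        raise ValueError("abeta42 and ptau must be positive concentrations")
    out = np.log10(ptau / abeta42)
    return out if out.ndim else float(out)


def fit_lda_axis(
    features: np.ndarray,
    labels: Sequence[int],
    feature_spec: Sequence = (),
    name: str = "user-axis",
) -> LinearCompositeDefinition:
    """Derive a linear composite axis from labeled data by two-class LDA.

    Parameters
    ----------
    features : (n, p) array
        Already-transformed feature matrix (apply any log10 scaling first,
        or pass ``feature_spec`` naming the columns and transforms so the
        returned definition can be applied to raw tables).
    labels : (n,) array of {0, 1}
        1 = patient class, 0 = control class.
    feature_spec : sequence of (column, FeatureTransform), optional
        Stored in the returned definition. When given, ``features`` must
        already be on the transformed scale of these specs.
    name : str
        Axis name for the returned definition.

    Returns
    -------
    LinearCompositeDefinition
        Unit-norm weight vector oriented so the patient class mean projects
        positive; intercept places the projected midpoint of the class means
        at 0; ``cth = 0``.

    Notes
    -----
    Fisher LDA with pooled within-class covariance and equal priors:
    ``w ∝ Σ_pooled⁻¹ (μ_patient − μ_control)``. A ridge ``εI`` with
    ``ε = 1e-6 · mean(diag(Σ))`` is added (with a warning) if the pooled
    covariance is singular.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("labels must align with feature rows")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be non-empty")
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} subjects, got {n}")

    mu1 = X[y == 1].mean(axis=0)
    mu0 = X[y == 0].mean(axis=0)
    delta = mu1 - mu0
    if np.allclose(delta, 0.0):
        raise DegenerateSeparationError("degenerate separation: identical class means")

    d1 = X[y == 1] - mu1
    d0 = X[y == 0] - mu0
    pooled = (d1.T @ d1 + d0.T @ d0) / (n - 2)
    # rank check via condition number on the symmetric pooled covariance
    if np.linalg.matrix_rank(pooled) < p:
        eps = 1e-6 * float(np.mean(np.diag(pooled)))
        if eps <= 0:
            eps = 1e-12
        warnings.warn(
            "singular pooled covariance; applying ridge regularization",
            RuntimeWarning,
        )
        pooled = pooled + eps * np.eye(p)

    w = np.linalg.solve(pooled, delta)
    w = w / np.linalg.norm(w)
    if w @ delta < 0:  # orient patient-positive
        w = -w
    intercept = -float(w @ (mu1 + mu0) / 2.0)

    spec = tuple(feature_spec) if feature_spec else tuple(
        (f"x{j}", FeatureTransform("identity")) for j in range(p)
    )
    if len(spec) != p:
        raise ValueError("feature_spec length must match feature columns")
    return LinearCompositeDefinition(
        name=name,
        features=spec,
        coefficients=tuple(float(v) for v in w),
        intercept=intercept,
        cth=0.0,
        provenance=f"lda-fit(n={n}, patients={n1}, controls={n0})",
    )


def classification_accuracy(scores, labels, cth: float) -> float:
    """Fraction of subjects whose (score > cth) status matches the patient label."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    return float(np.mean((s > cth).astype(int) == y))


def loocv_accuracy(features, labels, feature_spec=()) -> float:
    """Leave-one-out cross-validated accuracy of the LDA axis.

    Each subject is classified by an axis fit on the remaining n−1; the mean
    over subjects estimates the out-of-sample accuracy of the fitted rule.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n = X.shape[0]
    hits = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(set(ytr.tolist())) < 2:
            raise ValueError("leave-one-out fold with a single-class training set")
        axis = fit_lda_axis(X[mask], ytr, feature_spec)
        score = float(
            X[i] @ np.asarray(axis.coefficients, dtype=float) + axis.intercept
        )
        hits += int((score > axis.cth) == bool(y[i]))
    return hits / n
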