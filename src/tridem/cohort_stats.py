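"""Cohort-level statistical battery.

Three families of analyses accompany the trichotomy classification:

* covariate-adjusted association between biomarker pairs — OLS slope with
  standard error, plus the partial correlation of the two residual vectors
  after regressing each biomarker on the covariates (default covariates:
  age, sex, education, acquisition protocol);
* R²/AIC comparison of nested linear models predicting the cognition
  composite from the white-matter markers;
* the nine-group-pair × nine-hypothesis battery comparing subgroup unions
  (chi-squared test of proportions, two-sample t-test for means) with
  Bonferroni correction by the full battery size (9 × 9 = 81).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trichotomy import TrichotomyLabel

__all__ = [
    "DEFAULT_COVARIATES",
    "PartialCorrelationResult",
    "GroupComparisonResult",
    "HypothesisSpec",
    "DEFAULT_HYPOTHESES",
    "GROUP_PAIR_DEFINITIONS",
    "build_design_matrix",
    "residualize",
    "partial_correlation",
    "compare_models_aic",
    "define_group_pairs",
    "group_pair_tests",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "protocol")
P_FLOOR = 1e-300  # reporting floor; avoids log-underflow in downstream use


@dataclass(frozen=True)
class PartialCorrelationResult:
    biomarker1: str
    biomarker2: str
    covariates: tuple
    beta: float
    se: float
    r_partial: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparisonResult:
    pair_id: str
    hypothesis_id: str
    test_type: str  # "chi-squared" or "t-test"
    statistic: float
    p_raw: float
    p_adjusted: float
    n1: int
    n2: int
    testable: bool = True
    note: str = ""


def build_design_matrix(
    covariates: Optional[pd.DataFrame], add_intercept: bool = True
) -> pd.DataFrame:
    """Expand a covariate table to a numeric design matrix.

    Categorical/object columns (e.g. sex, protocol) become 0/1 indicator
    columns with the first level dropped; an intercept column is always
    included. Collinear columns are dropped with a warning.
    """
    if covariates is None or covariates.shape[1] == 0:
        n = 0 if covariates is None else len(covariates)
        X = pd.DataFrame(index=range(n) if covariates is None else covariates.index)
    else:
        parts = []
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
                parts.append(dummies)
            else:
                parts.append(s.astype(float).to_frame(col))
        X = pd.concat(parts, axis=1)
    if add_intercept:
        X.insert(0, "const", 1.0)
    # drop collinear columns by greedy rank check
    arr = X.to_numpy(dtype=float)
    keep = []
    for j in range(arr.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(arr[:, cand]) == len(cand):
            keep.append(j)
    if len(keep) < arr.shape[1]:
        dropped = [X.columns[j] for j in range(arr.shape[1]) if j not in keep]
        warnings.warn(
            f"dropping collinear design columns: {dropped}", RuntimeWarning
        )
        X = X.iloc[:, keep]
    return X


def residualize(y, covariates: Optional[pd.DataFrame] = None) -> np.ndarray:
    """OLS residuals of ``y`` on the covariates (intercept always included).

    The residuals have mean exactly zero (up to floating point) and are
    orthogonal to every design column.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if covariates is not None and len(covariates) != n:
        raise ValueError("y and covariates must align")
    X = build_design_matrix(covariates)
    if len(X) == 0:
        X = pd.DataFrame({"const": np.ones(n)})
    if n <= X.shape[1] + 1:
        raise ValueError("too few observations for the covariate design")
    beta, *_ = np.linalg.lstsq(X.to_numpy(dtype=float), yv, rcond=None)
    return yv - X.to_numpy(dtype=float) @ beta


def partial_correlation(
    x,
    y,
    covariates: Optional[pd.DataFrame] = None,
    name_x: str = "x",
    name_y: str = "y",
) -> PartialCorrelationResult:
    """Partial correlation of two biomarkers given covariates.

    ``r_partial`` is the Pearson correlation of the two OLS residual
    vectors; its p-value uses the t distribution with ``n − 2 − k`` degrees
    of freedom, k being the number of covariate columns (dummy-expanded,
    excluding the intercept). ``beta``/``se`` are the slope of ``y`` on
    ``x`` in the covariate-adjusted regression, mirroring how
    regression tables report the association alongside the partial r.
    """
    import statsmodels.api as sm

    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must align")
    n = xv.size
    rx = residualize(xv, covariates)
    ry = residualize(yv, covariates)
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        raise ValueError("zero-variance residuals")
    r = float(np.corrcoef(rx, ry)[0, 1])

    X = build_design_matrix(covariates)
    if len(X) == 0:
        X = pd.DataFrame({"const": np.ones(n)})
    k = X.shape[1] - 1
    df = n - 2 - k
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-15))  # |r|=1 gives p at the floor
    p = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)

    design = X.copy()
    design[name_x] = xv
    fit = sm.OLS(yv, design.to_numpy(dtype=float)).fit()
    beta = float(fit.params[-1])
    se = float(fit.bse[-1])
    return PartialCorrelationResult(
        biomarker1=name_y,
        biomarker2=name_x,
        covariates=tuple(covariates.columns) if covariates is not None else (),
        beta=beta,
        se=se,
        r_partial=r,
        p=float(p),
        n=n,
    )


def compare_models_aic(y, predictor_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """R² and AIC for a family of linear models of the same response.

    AIC uses the Gaussian-likelihood convention
    ``n·ln(RSS/n) + 2·(k + 2)`` where k counts the predictors (the +2 covers
    the intercept and the error variance). Models are returned ranked by
    AIC ascending (most parsimonious fit first).
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    tss = float(np.sum((yv - yv.mean()) ** 2))
    rows = []
    for name, X in predictor_sets.items():
        Xd = pd.DataFrame(X)
        if len(Xd) != n:
            raise ValueError(f"model {name!r}: predictor rows must match y")
        k = Xd.shape[1]
        if n <= k + 2:
            raise ValueError(f"model {name!r}: need n > k + 2")
        design = np.column_stack([np.ones(n), Xd.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        rss = float(np.sum((yv - design @ beta) ** 2))
        r2 = 1.0 - rss / tss
        aic = n * np.log(rss / n) + 2.0 * (k + 2)
        rows.append({"model": name, "k": k, "r_squared": r2, "aic": aic})
    out = pd.DataFrame(rows).set_index("model").sort_values("aic")
    return out


L = TrichotomyLabel
#: The nine group-pair contrasts, each a (description, union1, union2) triple.
GROUP_PAIR_DEFINITIONS: Mapping[str, tuple] = {
    "G1": (
        "Cognition (low vs normal)",
        (L.bCL, L.bVD, L.bAD, L.bMX),
        (L.bCN, L.bCN_VD, L.bCN_AD, L.bCN_MX),
    ),
    "G2": (
        "Vascular disease (yes vs no)",
        (L.bVD, L.bMX, L.bCN_VD, L.bCN_MX),
        (L.bCN, L.bCN_AD, L.bCL, L.bAD),
    ),
    "G3": (
        "Alzheimer's disease (yes vs no)",
        (L.bAD, L.bMX, L.bCN_AD, L.bCN_MX),
        (L.bCN, L.bCN_VD, L.bCL, L.bVD),
    ),
    "G4": ("Cognition (low vs normal) for VD-yes", (L.bVD, L.bMX), (L.bCN_VD, L.bCN_MX)),
    "G5": ("Cognition (low vs normal) for AD-yes", (L.bAD, L.bMX), (L.bCN_AD, L.bCN_MX)),
    "G6": ("VD (yes vs no) for cognition-low", (L.bVD, L.bMX), (L.bCL, L.bAD)),
    "G7": ("VD (yes vs no) for AD-yes", (L.bMX, L.bCN_MX), (L.bAD, L.bCN_AD)),
    "G8": ("AD (yes vs no) for cognition-low", (L.bAD, L.bMX), (L.bCL, L.bVD)),
    "G9": ("AD (yes vs no) for VD-yes", (L.bMX, L.bCN_MX), (L.bVD, L.bCN_VD)),
}


def define_group_pairs(labels: Iterable) -> Mapping[str, tuple]:
    """Index sets for the nine subgroup contrasts, given per-subject labels.

    Returns ``{pair_id: (idx_group1, idx_group2)}`` where each element is an
    integer index array. The two sets in a pair are always disjoint.
    """
    vals = np.asarray([TrichotomyLabel(l).value for l in labels], dtype=object)
    out = {}
    for pid, (_desc, u1, u2) in GROUP_PAIR_DEFINITIONS.items():
        s1 = [l.value for l in u1]
        s2 = [l.value for l in u2]
        out[pid] = (
            np.flatnonzero(np.isin(vals, s1)),
            np.flatnonzero(np.isin(vals, s2)),
        )
    return out


@dataclass(frozen=True)
class HypothesisSpec:
    """One tested hypothesis: a variable and how it is compared.

    ``kind`` is ``"proportion"`` (chi-squared test on the 2×2 table of the
    indicator) or ``"mean"`` (two-sample t-test). For proportions,
    ``indicator`` maps the raw column to a boolean event.
    """

    hypothesis_id: str
    column: str
    kind: str
    indicator: Optional[callable] = None
    description: str = ""

    def event(self, values: pd.Series) -> np.ndarray:
        if self.indicator is None:
            return values.astype(bool).to_numpy()
        return np.asarray(self.indicator(values), dtype=bool)


#: The default nine-hypothesis battery over the auxiliary variables not used
#: in the composite scores: sex, APOE4 genotype, clinical severity (CDRSB and
#: its annual change) as proportions, hippocampal volume and brain atrophy as
#: means.
DEFAULT_HYPOTHESES: tuple = (
    HypothesisSpec("H1", "sex", "proportion", lambda s: s == "male", "male proportion"),
    HypothesisSpec("H2", "apoe4", "proportion", lambda s: s >= 1, "any APOE4 allele"),
    HypothesisSpec("H3", "apoe4", "proportion", lambda s: s == 2, "both APOE4 alleles"),
    HypothesisSpec("H4", "cdrsb", "proportion", lambda s: s > 0, "CDRSB above zero"),
    HypothesisSpec("H5", "cdrsb", "proportion", lambda s: s >= 1, "CDRSB at least 1"),
    HypothesisSpec(
        "H6", "delta_cdrsb", "proportion", lambda s: s > 0, "worsening CDRSB"
    ),
    HypothesisSpec(
        "H7", "delta_cdrsb", "proportion", lambda s: s >= 0.5, "fast-worsening CDRSB"
    ),
    HypothesisSpec("H8", "hv", "mean", None, "hippocampal volume"),
    HypothesisSpec("H9", "ba", "mean", None, "brain atrophy"),
)


def _chi2_proportions(e1: np.ndarray, e2: np.ndarray):
    """Chi-squared test (no continuity correction) of equal event proportions."""
    table = np.array(
        [
            [int(e1.sum()), int((~e1).sum())],
            [int(e2.sum()), int((~e2).sum())],
        ],
        dtype=float,
    )
    if np.any(table == 0):
        return None
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def group_pair_tests(
    data: pd.DataFrame,
    labels: Iterable,
    hypotheses: Sequence[HypothesisSpec] = DEFAULT_HYPOTHESES,
    correction_factor: Optional[int] = None,
    welch: bool = False,
) -> list:
    """Run the full pair × hypothesis battery with Bonferroni correction.

    Every (group pair, hypothesis) combination yields one
    :class:`GroupComparisonResult`; with the default nine pairs and nine
    hypotheses the correction factor is 81 and
    ``p_adjusted = min(1, p_raw × 81)``. Missing values in a hypothesis
    variable are dropped pairwise. A 2×2 table with an empty cell is
    reported as untestable rather than given a p-value. ``welch=False``
    uses the pooled-variance two-sample t-test.
    """
    labels = list(labels)
    if len(labels) != len(data):
        raise ValueError("labels must align with data rows")
    pairs = define_group_pairs(labels)
    if correction_factor is None:
        correction_factor = len(pairs) * len(hypotheses)
    results = []
    for pid, (idx1, idx2) in pairs.items():
        for hyp in hypotheses:
            if hyp.column not in data.columns:
                results.append(
                    GroupComparisonResult(
                        pid, hyp.hypothesis_id, hyp.kind, np.nan, np.nan, np.nan,
                        len(idx1), len(idx2), testable=False,
                        note=f"missing column: {hyp.column}",
                    )
                )
                continue
            v1 = data[hyp.column].iloc[idx1].dropna()
            v2 = data[hyp.column].iloc[idx2].dropna()
            if len(v1) == 0 or len(v2) == 0:
                results.append(
                    GroupComparisonResult(
                        pid, hyp.hypothesis_id, hyp.kind, np.nan, np.nan, np.nan,
                        len(v1), len(v2), testable=False, note="empty group",
                    )
                )
                continue
            if hyp.kind == "proportion":
                test = _chi2_proportions(hyp.event(v1), hyp.event(v2))
                if test is None:
                    warnings.warn(
                        f"{pid}/{hyp.hypothesis_id}: zero cell in the 2x2 "
                        "table; untestable",
                        RuntimeWarning,
                    )
                    results.append(
                        GroupComparisonResult(
                            pid, hyp.hypothesis_id, "chi-squared",
                            np.nan, np.nan, np.nan, len(v1), len(v2),
                            testable=False, note="zero cell",
                        )
                    )
                    continue
                stat, p = test
                test_type = "chi-squared"
            elif hyp.kind == "mean":
                stat, p = stats.ttest_ind(
                    v1.to_numpy(dtype=float),
                    v2.to_numpy(dtype=float),
                    equal_var=not welch,
                )
                stat, p = float(stat), float(p)
                test_type = "t-test"
            else:
                raise ValueError(f"unknown hypothesis kind: {hyp.kind!r}")
            p = max(p, P_FLOOR)
            results.append(
                GroupComparisonResult(
                    pid, hyp.hypothesis_id, test_type, stat, p,
                    min(1.0, p * correction_factor), len(v1), len(v2),
                )
            )
    return results


def comparison_results_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    """Tabulate battery results; pivot on (pair, hypothesis) for reports."""
    return pd.DataFrame([r.__dict__ for r in results])
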