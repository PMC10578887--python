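"""Uniform normalization transform (UNT): cutoff-anchored quantile mapping.

Each raw composite score is mapped to a normalized score in the open
interval (0,1) by a monotone, table-based transform calibrated on a cohort,
with three binding properties: the output lies strictly inside (0,1), the
clinical cutoff ``cth`` on the raw scale maps exactly to 0.5, and the
calibration sample is approximately uniform on each side of 0.5.

The construction used here is the minimal table-based map with those
properties (the piecewise-affine rescaling of an empirical CDF around the
cutoff):

1. ``estimate_cdf`` tabulates the empirical CDF of the calibration scores
   at their sorted unique values, with midrank tie handling and the
   ``(rank − 0.5)/n`` convention so tabulated values are strictly inside
   (0,1); values between knots are linearly interpolated.
2. ``build_unt`` rescales each side of the cutoff separately: with
   ``F0 = F(cth)``,

   ``CS_norm(x) = 0.5·F(x)/F0``                     for ``x ≤ cth``
   ``CS_norm(x) = 0.5 + 0.5·(F(x) − F0)/(1 − F0)``  for ``x > cth``

   which pins ``CS_norm(cth) = 0.5`` while preserving ranks and the mass on
   each side of the cutoff.
3. ``apply_unt`` interpolates the stored table; new subjects outside the
   calibration range are clamped to ``ε`` / ``1 − ε`` with
   ``ε = 1/(2·n_calibration)``, symmetric with the CDF convention.

Tables are fitted once on a calibration cohort, serialized to plain text,
and applied to new subjects without refitting.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EmpiricalCDF", "UNTTable", "estimate_cdf", "build_unt", "apply_unt"]

MIN_CALIBRATION_N = 20


@dataclass(frozen=True)
class EmpiricalCDF:
    """Tabulated empirical CDF: knots at sorted unique sample values.

    CDF values follow the midrank ``(rank − 0.5)/n`` convention, so they are
    strictly inside (0,1); between knots the CDF is linearly interpolated,
    and it is clipped to the first/last tabulated value outside the range.
    """

    knots: np.ndarray
    values: np.ndarray
    n: int

    def __call__(self, x):
        return np.interp(x, self.knots, self.values)


def estimate_cdf(raw_scores) -> EmpiricalCDF:
    """Tabulate the empirical CDF of a calibration sample.

    Requires at least 20 finite values and non-degenerate support. Ties get
    their midrank, e.g. scores {1,2,3,4} tabulate to {0.125, 0.375, 0.625,
    0.875}.
    """
    x = np.asarray(raw_scores, dtype=float).ravel()
    if x.size < MIN_CALIBRATION_N:
        raise ValueError(
            f"insufficient calibration sample: need >= {MIN_CALIBRATION_N}, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("calibration sample contains non-finite values")
    n = x.size
    # midranks via scipy, then collapse to unique knots
    ranks = stats.rankdata(x, method="average")
    cdf_vals = (ranks - 0.5) / n
    knots, idx = np.unique(x, return_index=True)
    if knots.size < 2:
        raise ValueError("degenerate support: all calibration scores identical")
    return EmpiricalCDF(knots=knots, values=cdf_vals[idx], n=n)


@dataclass(frozen=True)
class UNTTable:
    """Calibrated monotone raw → normalized mapping with the cutoff at 0.5."""

    axis: str
    knots_raw: np.ndarray
    knots_norm: np.ndarray
    cth_raw: float
    n_calibration: int
    epsilon: float

    def __post_init__(self) -> None:
        kr = np.asarray(self.knots_raw, dtype=float)
        kn = np.asarray(self.knots_norm, dtype=float)
        if kr.shape != kn.shape or kr.ndim != 1:
            raise ValueError("knot arrays must be aligned 1-D arrays")
        if np.any(np.diff(kr) <= 0) or np.any(np.diff(kn) <= 0):
            raise ValueError("knots must be strictly increasing")
        if kn[0] <= 0 or kn[-1] >= 1:
            raise ValueError("normalized knots must lie strictly inside (0,1)")

    # -- plain-text serialization ------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# axis: {self.axis}\n")
        buf.write(f"# cth_raw: {self.cth_raw!r}\n")
        buf.write(f"# n_calibration: {self.n_calibration}\n")
        buf.write(f"# epsilon: {self.epsilon!r}\n")
        buf.write("# raw\tnormalized\n")
        for r, v in zip(self.knots_raw, self.knots_norm):
            buf.write(f"{float(r)!r}\t{float(v)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "UNTTable":
        header = {}
        raw, norm = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            a, b = line.split("\t")
            raw.append(float(a))
            norm.append(float(b))
        return cls(
            axis=header.get("axis", ""),
            knots_raw=np.asarray(raw),
            knots_norm=np.asarray(norm),
            cth_raw=float(header["cth_raw"]),
            n_calibration=int(header["n_calibration"]),
            epsilon=float(header["epsilon"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "UNTTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_text(fh.read())


def build_unt(cdf: EmpiricalCDF, cth_raw: float, axis: str = "") -> UNTTable:
    """Build the cutoff-anchored normalization table from a tabulated CDF.

    ``cth_raw`` must lie strictly inside the calibration range so both
    halves of the rescaling are well defined.
    """
    cth_raw = float(cth_raw)
    if not (cdf.knots[0] < cth_raw < cdf.knots[-1]):
        raise ValueError(
            "cutoff not bracketed: cth_raw must lie strictly inside the "
            f"calibration range [{cdf.knots[0]:g}, {cdf.knots[-1]:g}]"
        )
    knots_raw = np.unique(np.append(cdf.knots, cth_raw))
    F = cdf(knots_raw)
    F0 = float(cdf(cth_raw))
    lower = knots_raw <= cth_raw
    knots_norm = np.empty_like(F)
    knots_norm[lower] = 0.5 * F[lower] / F0
    knots_norm[~lower] = 0.5 + 0.5 * (F[~lower] - F0) / (1.0 - F0)
    # pin the cutoff knot exactly (guards against rounding in the division)
    knots_norm[np.searchsorted(knots_raw, cth_raw)] = 0.5
    return UNTTable(
        axis=axis,
        knots_raw=knots_raw,
        knots_norm=knots_norm,
        cth_raw=cth_raw,
        n_calibration=cdf.n,
        epsilon=1.0 / (2.0 * cdf.n),
    )


def apply_unt(table: UNTTable, x):
    """Map raw score(s) through the normalization table.

    Inside the calibration range the map is strictly increasing linear
    interpolation between knots; values outside are clamped to
    ``epsilon`` / ``1 − epsilon`` (logged, since a frozen table is expected
    to be applied to new subjects near the calibration support). NaN inputs
    propagate as NaN.
    """
    xv = np.asarray(x, dtype=float)
    out = np.interp(xv, table.knots_raw, table.knots_norm)
    below = xv < table.knots_raw[0]
    above = xv > table.knots_raw[-1]
    n_out = int(np.sum(below) + np.sum(above))
    if n_out:
        logger.warning(
            "%d value(s) outside the %s calibration range; clamped to "
            "[epsilon, 1-epsilon]",
            n_out,
            table.axis or "UNT",
        )
    out = np.where(below, table.epsilon, out)
    out = np.where(above, 1.0 - table.epsilon, out)
    out = np.where(np.isnan(xv), np.nan, out)
    return out if out.ndim else float(out)
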