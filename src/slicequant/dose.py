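"""Radiochromic-film dose QA: optical-density-to-dose conversion and lateral
homogeneity scoring.

Scanned-film darkening (net optical density) is converted to dose through a
user-supplied monotone calibration curve; the homogeneity of the delivered
field over a region of interest is scored as the percentile-clipped
min-to-max dose ratio, ``H = 100 * D_low / D_high`` with the (2, 98)
percentiles by default.  The acceptance criterion for slice irradiation is
H >= 95% over the plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationCurve", "DoseMap", "od_to_dose", "homogeneity", "summarize_dose"]


@dataclass
class CalibrationCurve:
    """Monotone (net OD, dose) calibration nodes, piecewise-linear between."""

    od: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.od.ndim != 1 or self.od.size < 2 or self.od.shape != self.dose.shape:
            raise ValueError("curve needs >= 2 (od, dose) node pairs")
        if not (np.all(np.diff(self.od) > 0) and np.all(np.diff(self.dose) > 0)):
            raise ValueError("calibration nodes must be strictly increasing in OD and dose")

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def od_to_dose(net_od: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Convert a net-OD raster to dose by monotone piecewise-linear
    interpolation; calibration nodes map to their doses exactly.

    Values outside the calibrated OD range are clamped to the end nodes and
    reported with a warning rather than extrapolated.
    """
    od = np.asarray(net_od, dtype=float)
    n_out = int(((od < curve.od[0]) | (od > curve.od[-1])).sum())
    if n_out:
        warnings.warn(
            f"{n_out} OD value(s) outside the calibrated range "
            f"[{curve.od[0]}, {curve.od[-1]}]; clamped to the end nodes"
        )
    return np.interp(od, curve.od, curve.dose)


def homogeneity(
    dose: np.ndarray,
    roi: np.ndarray | None = None,
    clip_percentiles: tuple[float, float] = (2.0, 98.0),
) -> float:
    """Dose homogeneity over the ROI, in percent.

    H = 100 * D_low / D_high with D_low/D_high the clip-percentile doses
    within the ROI (default percentiles 2 and 98, robust to dust and film
    artifacts).  Invariant to global dose scaling.
    """
    dose = np.asarray(dose, dtype=float)
    if roi is None:
        roi = np.ones(dose.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != dose.shape:
        raise ValueError("ROI and dose raster shapes differ")
    vals = dose[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    lo, hi = clip_percentiles
    if not 0 <= lo < hi <= 100:
        raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
    d_low, d_high = np.percentile(vals, [lo, hi])
    if d_high == 0:
        raise ValueError("upper-percentile dose is zero: homogeneity undefined")
    return float(100.0 * d_low / d_high)


@dataclass
class DoseMap:
    """Dose raster with ROI and homogeneity summary."""

    dose: np.ndarray
    roi: np.ndarray
    homogeneity_pct: float
    d_min: float  # low clip-percentile dose within ROI
    d_max: float  # high clip-percentile dose within ROI
    d_mean: float

    def passes(self, criterion_pct: float = 95.0) -> bool:
        return self.homogeneity_pct >= criterion_pct


def summarize_dose(
    dose: np.ndarray,
    roi: np.ndarray | None = None,
    clip_percentiles: tuple[float, float] = (2.0, 98.0),
) -> DoseMap:
    """Build a :class:`DoseMap` summary (percentile-clipped min/max/mean and
    homogeneity) over the ROI."""
    dose = np.asarray(dose, dtype=float)
    if roi is None:
        roi = np.ones(dose.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    h = homogeneity(dose, roi, clip_percentiles)
    vals = dose[roi]
    d_low, d_high = np.percentile(vals, list(clip_percentiles))
    return DoseMap(
        dose=dose, roi=roi, homogeneity_pct=h,
        d_min=float(d_low), d_max=float(d_high), d_mean=float(vals.mean()),
    )
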