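"""Plate-assay arithmetic: LDH cytotoxicity and resazurin (PrestoBlue)
viability.

LDH released into the medium by lysed cells is read as blank-corrected
absorbance (490 nm minus 680 nm reference).  With a terminal detergent-lysis
step releasing the residual intracellular pool, the total signal

    LDH_total = LDH_lysis + sum_i LDH_day(i)

normalises each day's release to a cell-death fraction
``death(i) = LDH_day(i) / LDH_total`` and the surviving fraction is
``1 - cumulative death``.  The resazurin readout is corrected as
``A_sample(571) - A_sample(601) - (A_medium(571) - A_medium(601))``.
Time courses are normalised to day 1 in culture to absorb slice-size
variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AssayPlate

__all__ = [
    "SurvivalSeries",
    "ldh_signal",
    "survival_series",
    "survival_from_plate",
    "presto_corrected",
    "normalize_to_day1",
]


def ldh_signal(a490, a680):
    """Blank-corrected LDH absorbance: A(490 nm) - A(680 nm reference).

    Accepts scalars or arrays.  Negative results are physically dubious
    (reference exceeding signal) and are kept but warned about, so that the
    conservation identity of the survival series still holds exactly.
    """
    a490 = np.asarray(a490, dtype=float)
    a680 = np.asarray(a680, dtype=float)
    if not (np.isfinite(a490).all() and np.isfinite(a680).all()):
        raise ValueError("absorbances must be finite")
    out = a490 - a680
    if (out < 0).any():
        warnings.warn("negative blank-corrected LDH signal(s); retained, not floored")
    return out if out.ndim else float(out)


@dataclass
class SurvivalSeries:
    """Daily cell-death and surviving fractions from an LDH series.

    ``cell_death[i]`` is the fraction of the total pool lysed on day i+1
    (1-based days); ``surviving`` is the raw 1 - cumulative death, which can
    exit [0, 1] or increase only through negative noisy readings;
    ``surviving_clipped`` applies the documented repair policy at the final
    fraction stage only: clip to [0, 1], then enforce monotone decrease with
    a running minimum.  The raw series is the one that satisfies the exact
    conservation identity.
    """

    ldh_total: float
    cell_death: np.ndarray
    surviving: np.ndarray

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, len(self.cell_death) + 1)

    @property
    def surviving_clipped(self) -> np.ndarray:
        return np.minimum.accumulate(np.clip(self.surviving, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "cell_death": self.cell_death,
                "surviving": self.surviving,
                "surviving_clipped": self.surviving_clipped,
            }
        )


def survival_series(daily_ldh, ldh_lysis: float) -> SurvivalSeries:
    """Cumulative cytotoxicity from daily LDH signals plus the terminal lysis
    signal.

    total = lysis + sum(daily); death(i) = daily(i) / total;
    surviving(i) = 1 - sum_{j<=i} death(j).  Exact arithmetic: the sum of all
    daily deaths plus the final surviving fraction is 1 up to float rounding.
    """
    daily = np.asarray(daily_ldh, dtype=float)
    if daily.ndim != 1 or daily.size == 0:
        raise ValueError("daily_ldh must be a non-empty 1-D sequence")
    total = float(ldh_lysis + daily.sum())
    if total <= 0:
        raise ValueError(f"LDH total must be > 0, got {total}")
    death = daily / total
    surviving = 1.0 - np.cumsum(death)
    if (death < 0).any():
        warnings.warn("negative daily death fraction(s) from negative signals")
    return SurvivalSeries(ldh_total=total, cell_death=death, surviving=surviving)


def survival_from_plate(plate: AssayPlate, sample: str) -> SurvivalSeries:
    """Run the LDH arithmetic directly on an :class:`AssayPlate`."""
    wide = plate.daily_pairs(sample)
    daily = ldh_signal(wide[490].to_numpy(), wide[680].to_numpy())
    lys = plate.lysis_pair(sample)
    lysis_sig = ldh_signal(lys[490], lys[680])
    return survival_series(np.atleast_1d(daily), float(lysis_sig))


def presto_corrected(a_sample_571, a_sample_601, a_medium_571, a_medium_601):
    """Background-corrected resazurin absorbance.

    background = A_medium(571) - A_medium(601);
    corrected  = A_sample(571) - A_sample(601) - background.
    Negative backgrounds are handled algebraically (no flooring).
    """
    vals = [np.asarray(v, dtype=float) for v in
            (a_sample_571, a_sample_601, a_medium_571, a_medium_601)]
    if not all(np.isfinite(v).all() for v in vals):
        raise ValueError("absorbances must be finite")
    s571, s601, m571, m601 = vals
    background = m571 - m601
    out = s571 - s601 - background
    return out if out.ndim else float(out)


def normalize_to_day1(series) -> np.ndarray:
    """Normalise a per-day series to its day-1 value (index 0 maps to 1.0);
    a zero day-1 value leaves the ratio undefined and raises."""
    values = np.asarray(series, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if values[0] == 0:
        raise ValueError("day-1 value is zero: normalisation undefined")
    return values / values[0]
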