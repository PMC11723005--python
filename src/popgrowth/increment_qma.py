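"""Mean/periodic annual increment schedules and quantitative maturity age.

For a clone's mean-volume series V(t) over integer ages t:

* MAI(t) = V(t) / t       (mean annual increment, m^3/yr)
* PAI(t) = V(t) - V(t-1)  (periodic annual increment over the last
  year, indexed to the *later* age; undefined at the first age and
  across gaps in the series)

The quantitative maturity age (QMA) — the maximum-sustained-yield
harvest age — is the first age at which PAI has fallen back to MAI
(PAI <= MAI) after having exceeded it at some earlier age.  Requiring
the prior exceedance keeps a series that starts out already declining
from being assigned a spurious maturity at its first age; such series
are flagged ``IMMEDIATE_DECLINE``.  A series whose PAI never comes
back down to MAI within the measured range is ``NOT_REACHED``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .growth_data import TraitTable, aggregate_means

__all__ = [
    "IncrementSeries",
    "QmaResult",
    "compute_increments",
    "detect_qma",
    "QmaDetector",
    "qma_table",
]

FLAG_OK = "OK"
FLAG_NOT_REACHED = "NOT_REACHED"
FLAG_IMMEDIATE_DECLINE = "IMMEDIATE_DECLINE"
FLAG_NO_PAI = "NO_PAI"


@dataclass
class IncrementSeries:
    """MAI/PAI schedule of one clone.

    ``pai`` is NaN at the first age and wherever the preceding age is
    missing (gaps are never bridged).
    """

    clone_id: str
    ages: np.ndarray
    volume: np.ndarray
    mai: np.ndarray
    pai: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_id,
                "age": self.ages,
                "volume_m3": self.volume,
                "mai": self.mai,
                "pai": self.pai,
            }
        )


@dataclass
class QmaResult:
    clone_id: str
    qma_age: int | None
    volume_at_qma: float | None
    flag: str = FLAG_OK
    #: ages bracketing the MAI/PAI crossing, e.g. (12, 13)
    bracket: tuple[int, int] | None = None
    #: linearly interpolated real-valued crossing age (diagnostic)
    crossing_interp: float | None = None


def compute_increments(clone_id: str, ages, volumes) -> IncrementSeries:
    """MAI and PAI from a clone's per-age mean volume series.

    ``ages`` must be strictly increasing positive integers with at
    least two entries.  PAI is only defined between consecutive
    integer ages; a gap leaves PAI NaN at the age after the gap.
    """
    ages = np.asarray(ages, dtype=int)
    volumes = np.asarray(volumes, dtype=float)
    if ages.ndim != 1 or ages.shape != volumes.shape:
        raise ValueError("ages and volumes must be 1-d and equal length")
    if len(ages) < 2:
        raise ValueError("insufficient series: need at least two ages")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")

    mai = volumes / ages
    pai = np.full(len(ages), np.nan)
    consecutive = np.diff(ages) == 1
    pai[1:][consecutive] = np.diff(volumes)[consecutive]
    return IncrementSeries(clone_id=str(clone_id), ages=ages, volume=volumes, mai=mai, pai=pai)


def _smooth_pai(pai: np.ndarray) -> np.ndarray:
    """Centred 3-point moving average, NaN-aware, shrinking at edges."""
    out = np.full_like(pai, np.nan)
    for i in range(len(pai)):
        window = pai[max(i - 1, 0) : i + 2]
        window = window[~np.isnan(window)]
        if len(window) and not np.isnan(pai[i]):
            out[i] = window.mean()
    return out


def detect_qma(inc: IncrementSeries, smooth: bool = False) -> QmaResult:
    """Locate the quantitative maturity age of an increment series.

    Deterministic: scans ages in order; QMA is the smallest age t with
    PAI(t) <= MAI(t) after some earlier age had PAI > MAI.  Ties
    (PAI exactly equal to MAI) count as a crossing at that age.
    ``smooth`` applies a 3-point moving average to PAI before
    detection (off by default).
    """
    pai = _smooth_pai(inc.pai) if smooth else inc.pai
    defined = ~np.isnan(pai)
    if not defined.any():
        warnings.warn(f"{inc.clone_id}: no PAI values; QMA undefined", stacklevel=2)
        return QmaResult(inc.clone_id, None, None, flag=FLAG_NO_PAI)

    exceeded = False
    prev_idx = None
    for i in np.flatnonzero(defined):
        if exceeded and pai[i] <= inc.mai[i]:
            age = int(inc.ages[i])
            bracket = (int(inc.ages[prev_idx]), age) if prev_idx is not None else None
            interp = None
            if prev_idx is not None:
                d0 = pai[prev_idx] - inc.mai[prev_idx]
                d1 = pai[i] - inc.mai[i]
                if d0 > d1:  # guaranteed d0 > 0 >= d1 at a crossing
                    frac = d0 / (d0 - d1)
                    interp = float(inc.ages[prev_idx] + frac * (inc.ages[i] - inc.ages[prev_idx]))
            return QmaResult(
                inc.clone_id,
                qma_age=age,
                volume_at_qma=float(inc.volume[i]),
                flag=FLAG_OK,
                bracket=bracket,
                crossing_interp=interp,
            )
        if pai[i] > inc.mai[i]:
            exceeded = True
            prev_idx = i
        else:
            prev_idx = i

    if exceeded:
        return QmaResult(inc.clone_id, None, None, flag=FLAG_NOT_REACHED)
    # PAI never rose above MAI: declining from the outset
    return QmaResult(inc.clone_id, None, None, flag=FLAG_IMMEDIATE_DECLINE)


class QmaDetector(BaseEstimator):
    """Per-clone MAI/PAI schedules and maturity ages from a trait table.

    Parameters
    ----------
    smooth : bool, default False
        Apply a 3-point moving average to PAI before crossing
        detection.

    Attributes
    ----------
    increments_ : dict[str, IncrementSeries]
        Per-clone schedules computed from clone-mean volumes.
    results_ : pandas.DataFrame
        One row per clone: ``clone_id, qma_age, volume_at_qma, flag,
        crossing_interp``.  ``qma_age`` is NaN for clones flagged
        ``NOT_REACHED`` (the published convention prints a dash).
    """

    def __init__(self, smooth: bool = False):
        self.smooth = smooth

    def fit(self, table: TraitTable, y=None):
        means = aggregate_means(table, level="clone")
        self.increments_ = {}
        results = []
        for clone, sub in means.groupby("group"):
            sub = sub.sort_values("age")
            if len(sub) < 2:
                warnings.warn(f"{clone}: single age, skipped", stacklevel=2)
                continue
            inc = compute_increments(clone, sub["age"].values, sub["volume_m3"].values)
            self.increments_[str(clone)] = inc
            res = detect_qma(inc, smooth=self.smooth)
            results.append(
                {
                    "clone_id": res.clone_id,
                    "qma_age": res.qma_age if res.qma_age is not None else np.nan,
                    "volume_at_qma": res.volume_at_qma,
                    "flag": res.flag,
                    "crossing_interp": res.crossing_interp,
                }
            )
        self.results_ = pd.DataFrame(results)
        return self

    def fit_predict(self, table: TraitTable) -> pd.DataFrame:
        return self.fit(table).results_


def qma_table(table: TraitTable, smooth: bool = False) -> pd.DataFrame:
    """One-call wrapper: per-clone QMA summary frame."""
    return QmaDetector(smooth=smooth).fit_predict(table)
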