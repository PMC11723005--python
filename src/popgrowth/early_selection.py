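"""Age-age correlation and early-selection-efficiency scoring.

Early selection in tree breeding trades accuracy for time: a trait
measured at an early age ``t_l`` predicts the same trait at a mature
reference age ``t_e`` with correlation ``Rp`` (computed across
genetic entries — clone means by default), and the early selection
efficiency scales that accuracy by the years saved:

    ESE = Rp * t_e / t_l

ESE > 1 means selecting early beats waiting, even after discounting
the imperfect correlation.  The optimal early-selection window is the
earliest run of consecutive ages where the correlation is both strong
(Rp above a threshold) and statistically significant — in joint mode,
in *both* hybrid populations at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .growth_data import TraitTable
from .association import pearson

__all__ = [
    "AgeAgeCorrelation",
    "SelectionWindow",
    "age_age_table",
    "ese_score",
    "optimal_window",
]


def ese_score(r: float, early_age: float, late_age: float) -> float:
    """Early selection efficiency: Rp scaled by late/early age ratio."""
    if early_age <= 0 or late_age <= 0:
        raise ValueError("ages must be positive")
    return r * late_age / early_age


class AgeAgeCorrelation(BaseEstimator):
    """Age-age correlation table of one trait against a mature age.

    Parameters
    ----------
    trait : str, default "dbh_cm"
        Column to correlate; DBH is the usual choice because it is
        the cheapest trait to measure accurately.
    late_age : int, default 14
        Mature reference age t_e (late quantitative maturity in the
        reference trial).
    unit : {"clone_mean", "tree"}, default "clone_mean"
        Pairing unit.  Clone means are stable against tree-level
        mortality; tree-level pairing uses (clone, block, tree) ids.

    Attributes
    ----------
    rows_ : pandas.DataFrame
        One row per cross_type x early age (2 .. late_age - 1):
        ``cross_type, early_age, late_age, r, n, p_value, stars, ese``.
    """

    def __init__(self, trait: str = "dbh_cm", late_age: int = 14, unit: str = "clone_mean"):
        self.trait = trait
        self.late_age = late_age
        self.unit = unit

    def fit(self, table: TraitTable, y=None):
        if self.unit not in ("clone_mean", "tree"):
            raise ValueError("unit must be 'clone_mean' or 'tree'")
        df = table.data
        if self.late_age not in set(df["age"]):
            raise ValueError(f"late_age {self.late_age} absent from data")
        if self.unit == "clone_mean":
            unit_cols = ["clone_id"]
            values = df.groupby(["cross_type", "clone_id", "age"], as_index=False)[
                self.trait
            ].mean()
        else:
            unit_cols = ["clone_id", "block", "tree_id"]
            values = df[["cross_type", *unit_cols, "age", self.trait]]

        rows = []
        for cross, sub in values.groupby("cross_type"):
            wide = sub.pivot_table(index=unit_cols, columns="age", values=self.trait)
            if self.late_age not in wide.columns:
                continue
            late = wide[self.late_age]
            for early in range(2, self.late_age):
                if early not in wide.columns:
                    continue
                pair = pd.concat([wide[early], late], axis=1).dropna()
                if len(pair) < 3:
                    continue
                cr = pearson(pair.iloc[:, 0], pair.iloc[:, 1])
                rows.append(
                    {
                        "cross_type": str(cross),
                        "early_age": early,
                        "late_age": self.late_age,
                        "r": cr.r,
                        "n": cr.n,
                        "p_value": cr.p_value,
                        "stars": cr.stars,
                        "ese": ese_score(cr.r, early, self.late_age),
                    }
                )
        self.rows_ = pd.DataFrame(rows).sort_values(["cross_type", "early_age"]).reset_index(
            drop=True
        )
        return self


def age_age_table(
    table: TraitTable,
    trait: str = "dbh_cm",
    late_age: int = 14,
    unit: str = "clone_mean",
) -> pd.DataFrame:
    """One-call wrapper over :class:`AgeAgeCorrelation`."""
    return AgeAgeCorrelation(trait=trait, late_age=late_age, unit=unit).fit(table).rows_


@dataclass
class SelectionWindow:
    start_age: int | None
    end_age: int | None
    min_ese: float | None
    flag: str = "OK"

    @property
    def empty(self) -> bool:
        return self.start_age is None


def optimal_window(
    rows: pd.DataFrame,
    rp_min: float = 0.50,
    require_significance: bool = True,
    joint: bool = True,
) -> SelectionWindow:
    """Earliest maximal run of consecutive qualifying early ages.

    An age qualifies when ``r >= rp_min`` and (if required) p < 0.05.
    In joint mode every cross type present in ``rows`` must qualify
    at that age; in single mode pass rows of one population.  The
    returned window is annotated with the minimum ESE over the run.
    Deterministic; returns an empty window flagged
    ``NONE_QUALIFIES`` when no age qualifies.
    """
    if rows.empty:
        return SelectionWindow(None, None, None, flag="NONE_QUALIFIES")
    crosses = rows["cross_type"].unique() if joint else [None]

    def qualifies(age: int) -> bool:
        sub = rows[rows["early_age"] == age]
        if joint:
            if set(sub["cross_type"]) != set(crosses):
                return False
        ok = sub["r"] >= rp_min
        if require_significance:
            ok &= sub["p_value"] < 0.05
        return bool(len(sub) and ok.all())

    ages = sorted(rows["early_age"].unique())
    start = None
    for i, age in enumerate(ages):
        if qualifies(age):
            start = age
            run = [age]
            for nxt in ages[i + 1 :]:
                if nxt == run[-1] + 1 and qualifies(nxt):
                    run.append(nxt)
                else:
                    break
            ese_min = float(rows[rows["early_age"].isin(run)]["ese"].min())
            return SelectionWindow(start_age=start, end_age=run[-1], min_ese=ese_min)
    return SelectionWindow(None, None, None, flag="NONE_QUALIFIES")
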