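"""Survival filtering, clone ranking/selection and stability reporting.

The selection stage mirrors standard first-generation clonal
screening practice:

1. Candidate clones must clear a cutting-survival threshold
   (default: survival rate >= 60%, inclusive).
2. Survivors are ranked by clone-mean stem volume at a mature
   reference age and the top ``floor(rate * n)`` (minimum 1) are
   selected; ties break on higher DBH, then lexicographic clone id.
3. Stability is reported as the coefficient of variation of
   tree-level volume, ``CV = 100 * sd / mean`` (sample sd, n-1
   denominator): a selected clone should vary less than its source
   population.

Above/below-population-mean flags are emitted per trait; for HDR the
favourable direction is LOW (a stockier stem is more wind-stable), so
its flag is inverted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .growth_data import TraitTable

__all__ = [
    "SurvivalRecord",
    "SurvivalFilterResult",
    "read_survival",
    "filter_by_survival",
    "CloneSelector",
    "select_top_clones",
    "volume_cv",
]

#: traits where a value below the population mean is the good outcome
LOWER_IS_BETTER = {"hdr"}


@dataclass(frozen=True)
class SurvivalRecord:
    """Cutting-survival bookkeeping for one clone in one cross."""

    clone_id: str
    cross_type: str
    cuttings_planted: int
    cuttings_surviving: int

    @property
    def survival_rate(self) -> float:
        """Survival as a percentage of cuttings planted."""
        return 100.0 * self.cuttings_surviving / self.cuttings_planted


@dataclass
class SurvivalFilterResult:
    retained: list[str]
    counts_by_cross: dict[str, int]
    rejected: list[str] = field(default_factory=list)
    #: (clone_id, cross_type) keys seen more than once — surfaced, not resolved
    duplicates: list[tuple[str, str]] = field(default_factory=list)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival CSV: clone_id, cross_type, cuttings_planted, cuttings_surviving."""
    df = pd.read_csv(path, comment="#")
    needed = ["clone_id", "cross_type", "cuttings_planted", "cuttings_surviving"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return [
        SurvivalRecord(str(r.clone_id), str(r.cross_type), int(r.cuttings_planted),
                       int(r.cuttings_surviving))
        for r in df.itertuples()
    ]


def filter_by_survival(
    records: list[SurvivalRecord],
    threshold: float = 60.0,
    inclusive: bool = True,
) -> SurvivalFilterResult:
    """Retain clones whose survival rate clears the threshold.

    Inclusive by default (>= 60% retains a clone at exactly 60%).
    Records with zero cuttings planted are rejected with a warning.
    Duplicate (clone_id, cross_type) keys are surfaced in the result
    rather than silently merged.
    """
    seen: set[tuple[str, str]] = set()
    duplicates: list[tuple[str, str]] = []
    retained: list[str] = []
    rejected: list[str] = []
    counts: dict[str, int] = {}
    for rec in records:
        key = (rec.clone_id, rec.cross_type)
        if key in seen:
            duplicates.append(key)
        seen.add(key)
        if rec.cuttings_planted <= 0:
            warnings.warn(f"{rec.clone_id}: zero cuttings planted, record rejected",
                          stacklevel=2)
            continue
        if rec.cuttings_surviving < 0 or rec.cuttings_surviving > rec.cuttings_planted:
            raise ValueError(f"{rec.clone_id}: surviving outside [0, planted]")
        rate = rec.survival_rate
        ok = rate >= threshold if inclusive else rate > threshold
        if ok:
            retained.append(rec.clone_id)
            counts[rec.cross_type] = counts.get(rec.cross_type, 0) + 1
        else:
            rejected.append(rec.clone_id)
    return SurvivalFilterResult(
        retained=retained, counts_by_cross=counts, rejected=rejected, duplicates=duplicates
    )


def volume_cv(table: TraitTable, level: str = "cross_type", reference_age: int | None = None) -> pd.DataFrame:
    """Coefficient of variation (%) of tree-level volume per group.

    CV = 100 * sample sd / mean at the reference age (default: final
    measured age).  Groups with fewer than two trees get NaN and a
    flag.  ``cv_pct_display`` rounds to whole percent for reporting.
    """
    if level not in ("clone", "cross_type"):
        raise ValueError("level must be 'clone' or 'cross_type'")
    if not table.has_traits:
        raise ValueError("traits not derived; call derive_traits first")
    age = reference_age if reference_age is not None else max(table.ages)
    key = "clone_id" if level == "clone" else "cross_type"
    sub = table.data[table.data["age"] == age]
    rows = []
    for group, g in sub.groupby(key):
        v = g["volume_m3"].to_numpy()
        if len(v) < 2:
            rows.append({"group": str(group), "n": len(v), "cv_pct": np.nan,
                         "cv_pct_display": np.nan, "flag": "UNDEFINED"})
            continue
        cv = 100.0 * v.std(ddof=1) / v.mean()
        rows.append({"group": str(group), "n": len(v), "cv_pct": cv,
                     "cv_pct_display": round(cv), "flag": "OK"})
    return pd.DataFrame(rows)


class CloneSelector(BaseEstimator):
    """Rank clones on a mature-age criterion and select the top fraction.

    Parameters
    ----------
    rate : float, default 0.25
        Selection rate in (0, 1]; ``floor(rate * n)`` clones are
        selected, with a minimum of one.
    reference_age : int or None
        Age at which clone means are compared; None means the final
        measured age.
    criterion : str, default "volume_m3"
        Trait column used for ranking.

    Attributes
    ----------
    selected_ : list of clone ids, ranking order.
    report_ : dict — full selection report (per-clone mature trait
        means, above-mean flags, per-clone and per-population volume
        CV, population means).
    """

    def __init__(self, rate: float = 0.25, reference_age: int | None = None,
                 criterion: str = "volume_m3"):
        self.rate = rate
        self.reference_age = reference_age
        self.criterion = criterion

    def fit(self, table: TraitTable, y=None):
        if not (0 < self.rate <= 1):
            raise ValueError("rate must be in (0, 1]")
        if not table.has_traits:
            raise ValueError("traits not derived; call derive_traits first")
        age = self.reference_age if self.reference_age is not None else max(table.ages)
        sub = table.data[table.data["age"] == age]
        all_clones = set(table.clones)
        present = set(sub["clone_id"])
        skipped = sorted(all_clones - present)
        if skipped:
            warnings.warn(
                f"clones missing reference age {age}, excluded: {skipped}", stacklevel=2
            )

        means = sub.groupby(["clone_id", "cross_type"], as_index=False)[
            ["dbh_cm", "height_m", "hdr", "volume_m3"]
        ].mean()
        means = means.sort_values(
            by=[self.criterion, "dbh_cm", "clone_id"],
            ascending=[False, False, True],
        ).reset_index(drop=True)

        n = len(means)
        n_select = max(1, math.floor(self.rate * n))
        selected = means.head(n_select)

        pop_means = sub.groupby("cross_type")[["dbh_cm", "height_m", "hdr", "volume_m3"]].mean()
        cv_clone = volume_cv(table, level="clone", reference_age=age).set_index("group")
        cv_pop = volume_cv(table, level="cross_type", reference_age=age).set_index("group")

        per_clone = []
        for row in selected.itertuples():
            pm = pop_means.loc[row.cross_type]
            flags = {}
            for trait in ("dbh_cm", "height_m", "hdr", "volume_m3"):
                val, mean = getattr(row, trait), pm[trait]
                favourable = val < mean if trait in LOWER_IS_BETTER else val > mean
                flags[trait] = "favourable" if favourable else "unfavourable"
            per_clone.append(
                {
                    "clone_id": row.clone_id,
                    "cross_type": row.cross_type,
                    "dbh_cm": row.dbh_cm,
                    "height_m": row.height_m,
                    "hdr": row.hdr,
                    "volume_m3": row.volume_m3,
                    "volume_cv_pct": float(cv_clone["cv_pct"].get(row.clone_id, np.nan)),
                    "vs_population_mean": flags,
                }
            )

        self.selected_ = selected["clone_id"].tolist()
        self.report_ = {
            "reference_age": int(age),
            "selection_rate": self.rate,
            "criterion": self.criterion,
            "n_candidates": n,
            "n_selected": n_select,
            "excluded_missing_reference_age": skipped,
            "selected": per_clone,
            "population": {
                cross: {
                    **{t: float(pop_means.loc[cross, t])
                       for t in ("dbh_cm", "height_m", "hdr", "volume_m3")},
                    "volume_cv_pct": float(cv_pop["cv_pct"].get(cross, np.nan)),
                }
                for cross in pop_means.index
            },
        }
        return self


def select_top_clones(
    table: TraitTable,
    reference_age: int | None = None,
    rate: float = 0.25,
    criterion: str = "volume_m3",
) -> dict:
    """One-call wrapper over :class:`CloneSelector`; returns the report."""
    sel = CloneSelector(rate=rate, reference_age=reference_age, criterion=criterion).fit(table)
    return sel.report_
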