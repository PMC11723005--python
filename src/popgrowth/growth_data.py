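"""Trial measurement tables and derived stem traits.

A progeny-trial measurement table is long format: one row per tree per
year, with clone identity, cross type (direct ``DxM`` or reciprocal
``MxD``), block, tree id, age in years since planting, diameter at
breast height (DBH, cm) and total height (m).  From DBH and height
three standard stem traits are derived:

* height-to-diameter ratio ``HDR = H / DBH`` (m over cm, so mature
  poplar values sit around 0.6-0.8; lower means a stockier, more
  wind-stable stem),
* basal area ``G = pi * (DBH/100)**2 / 4`` in square metres,
* stem volume ``V = G * H * F`` with a fixed breast-height form
  factor ``F`` (default 0.44) converting cylinder volume to stem
  volume.

The in-memory container is a :class:`TraitTable`: a pandas DataFrame
plus provenance metadata (source path, form factor, rejected-row
accounting, per-clone age gaps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "REQUIRED_COLUMNS",
    "DERIVED_COLUMNS",
    "DEFAULT_FORM_FACTOR",
    "TraitTable",
    "TraitDeriver",
    "basal_area",
    "stem_volume",
    "read_measurements",
    "derive_traits",
    "aggregate_means",
    "write_traits",
]

REQUIRED_COLUMNS = (
    "clone_id",
    "cross_type",
    "block",
    "tree_id",
    "age",
    "dbh_cm",
    "height_m",
)
DERIVED_COLUMNS = ("hdr", "basal_area_m2", "volume_m3")
KEY_COLUMNS = ("clone_id", "block", "tree_id", "age")
CROSS_TYPES = ("DxM", "MxD")

#: Breast-height form factor for stem volume (dimensionless).
DEFAULT_FORM_FACTOR = 0.44


def basal_area(dbh_cm):
    """Breast-height basal area in m^2 from DBH in cm: pi * d^2 / 4."""
    d_m = np.asarray(dbh_cm, dtype=float) / 100.0
    return math.pi * d_m**2 / 4.0


def stem_volume(dbh_cm, height_m, form_factor: float = DEFAULT_FORM_FACTOR):
    """Stem volume in m^3: basal area x height x form factor."""
    return basal_area(dbh_cm) * np.asarray(height_m, dtype=float) * form_factor


@dataclass
class TraitTable:
    """A measurement table plus provenance metadata.

    ``data`` holds one row per tree per year.  Raw tables carry the
    seven required columns; :func:`derive_traits` appends ``hdr``,
    ``basal_area_m2`` and ``volume_m3``.
    """

    data: pd.DataFrame
    form_factor: float | None = None
    source: str | None = None
    n_rejected: int = 0
    rejection_log: list[str] = field(default_factory=list)

    @property
    def has_traits(self) -> bool:
        return all(c in self.data.columns for c in DERIVED_COLUMNS)

    @property
    def ages(self) -> list[int]:
        return sorted(int(a) for a in self.data["age"].unique())

    @property
    def clones(self) -> list[str]:
        return sorted(self.data["clone_id"].unique())

    def age_gaps(self) -> dict[str, list[int]]:
        """Missing ages inside each clone's own measured span.

        Gaps (dead-tree truncation is not a gap; a hole in the middle
        of a clone's series is) are recorded and surfaced here, never
        silently filled.
        """
        gaps: dict[str, list[int]] = {}
        for clone, sub in self.data.groupby("clone_id"):
            present = set(int(a) for a in sub["age"].unique())
            full = range(min(present), max(present) + 1)
            missing = [a for a in full if a not in present]
            if missing:
                gaps[str(clone)] = missing
        return gaps

    def copy(self) -> "TraitTable":
        return TraitTable(
            data=self.data.copy(),
            form_factor=self.form_factor,
            source=self.source,
            n_rejected=self.n_rejected,
            rejection_log=list(self.rejection_log),
        )


def _validate_frame(df: pd.DataFrame, source: str) -> TraitTable:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    df = df.loc[:, list(REQUIRED_COLUMNS) + [c for c in DERIVED_COLUMNS if c in df.columns]].copy()
    df["clone_id"] = df["clone_id"].astype(str)
    df["tree_id"] = df["tree_id"].astype(str)
    df["cross_type"] = df["cross_type"].astype(str)
    bad_cross = sorted(set(df["cross_type"]) - set(CROSS_TYPES))
    if bad_cross:
        raise ValueError(f"unknown cross_type value(s): {bad_cross}; expected {CROSS_TYPES}")
    df["block"] = df["block"].astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    for col in ("dbh_cm", "height_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    log: list[str] = []
    bad = (
        df["dbh_cm"].isna()
        | df["height_m"].isna()
        | (df["dbh_cm"] <= 0)
        | (df["height_m"] <= 0)
        | (df["age"] <= 0)
    )
    n_rejected = int(bad.sum())
    if n_rejected:
        for idx, row in df.loc[bad].iterrows():
            log.append(
                f"row {idx}: rejected (clone={row['clone_id']}, age={row['age']}, "
                f"dbh={row['dbh_cm']}, height={row['height_m']}): "
                "non-positive or missing measurement"
            )
        warnings.warn(
            f"{source}: rejected {n_rejected} row(s) with non-positive or missing values",
            stacklevel=3,
        )
        df = df.loc[~bad]

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (clone_id, block, tree_id, age) key(s): {keys[:5]}")

    return TraitTable(
        data=df.reset_index(drop=True),
        source=source,
        n_rejected=n_rejected,
        rejection_log=log,
    )


def read_measurements(
    path: str | Path,
    column_aliases: Mapping[str, str] | None = None,
) -> TraitTable:
    """Read a long-format measurement CSV into a :class:`TraitTable`.

    Parameters
    ----------
    path:
        CSV with header; lines starting with ``#`` are treated as
        comments (provenance blocks written by this package).
    column_aliases:
        Optional mapping from the file's column names to the canonical
        names, e.g. ``{"DBH_cm": "dbh_cm"}``.

    Raises
    ------
    ValueError
        If a required column is absent (named in the message) or a
        duplicate (clone, block, tree, age) key is found.  Rows with
        non-positive DBH/height are rejected with a warning and
        counted in ``n_rejected``, not raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if column_aliases:
        df = df.rename(columns=dict(column_aliases))
    return _validate_frame(df, source=str(path))


def table_from_frame(df: pd.DataFrame, source: str = "<memory>") -> TraitTable:
    """Validate an in-memory DataFrame into a :class:`TraitTable`."""
    return _validate_frame(df, source=source)


class TraitDeriver(BaseEstimator, TransformerMixin):
    """Stateless transformer appending HDR, basal area and volume.

    Parameters
    ----------
    form_factor : float, default 0.44
        Breast-height form factor used in the volume equation.
    """

    def __init__(self, form_factor: float = DEFAULT_FORM_FACTOR):
        self.form_factor = form_factor

    def fit(self, X, y=None):
        if not self.form_factor > 0:
            raise ValueError("form_factor must be positive")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["hdr"] = out["height_m"] / out["dbh_cm"]
        out["basal_area_m2"] = basal_area(out["dbh_cm"])
        out["volume_m3"] = out["basal_area_m2"] * out["height_m"] * self.form_factor
        return out


def derive_traits(table: TraitTable, form_factor: float = DEFAULT_FORM_FACTOR) -> TraitTable:
    """Return a new table with HDR, basal area and volume populated."""
    deriver = TraitDeriver(form_factor=form_factor).fit(None)
    out = table.copy()
    out.data = deriver.transform(table.data)
    out.form_factor = form_factor
    return out


def aggregate_means(table: TraitTable, level: str = "cross_type") -> pd.DataFrame:
    """Per-group, per-age means of the measured and derived traits.

    ``level`` is ``"clone"`` or ``"cross_type"``.  Group means are
    means of per-tree values — in particular mean volume is the mean
    of per-tree volumes, never the volume formula applied to mean DBH
    and height (Jensen's inequality makes those differ).  Groups with
    no trees at an age are simply absent.
    """
    if level not in ("clone", "cross_type"):
        raise ValueError("level must be 'clone' or 'cross_type'")
    if not table.has_traits:
        raise ValueError("traits not derived; call derive_traits first")
    if table.data.empty:
        warnings.warn("aggregate_means on an empty table", stacklevel=2)
        return pd.DataFrame(
            columns=["group", "age", "dbh_cm", "height_m", "hdr", "volume_m3", "n"]
        )
    key = "clone_id" if level == "clone" else "cross_type"
    grouped = table.data.groupby([key, "age"])
    out = grouped[["dbh_cm", "height_m", "hdr", "volume_m3"]].mean()
    out["n"] = grouped.size()
    out = out.reset_index().rename(columns={key: "group"})
    return out.sort_values(["group", "age"]).reset_index(drop=True)


def write_traits(
    table: TraitTable,
    path: str | Path,
    provenance: Iterable[str] = (),
) -> None:
    """Write a table to CSV; provenance lines go first, '#'-prefixed."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, index=False)
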