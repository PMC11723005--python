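"""Published summary values from the reference progeny trial.

The package's worked examples are anchored to the 17-year Liaoning
trial of reciprocal *Populus deltoides* 'DD-109' x *P. maximowiczii*
hybrids: 10 direct-cross (DxM) and 7 reciprocal-cross (MxD) clones
screened from 23 candidates by cutting survival.  The per-tree
measurements of that trial are not publicly deposited, but its
published summary tables are, and they serve as small worked-example
inputs: survival counts, mature-age clone trait means, the DBH
age-age correlation schedule, and per-clone quantitative maturity
ages.

These loaders return plain pandas objects / record lists; nothing
here is simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .selection_pipeline import SurvivalRecord

__all__ = [
    "load_survival_reference",
    "load_age_age_reference",
    "load_mature_traits_reference",
    "load_qma_reference",
]

# clone_id, cross_type, cuttings planted, cuttings surviving.
# MD-19 appears twice exactly as published (once under each cross
# type, with different counts); consumers surface the duplicate key
# instead of resolving it.
_SURVIVAL = [
    ("DM-9-22", "DxM", 20, 18),
    ("DM-9-16", "DxM", 20, 16),
    ("DM-9-18", "DxM", 20, 16),
    ("DM-9-24", "DxM", 20, 16),
    ("DM-9-8", "DxM", 20, 16),
    ("DM-9-25", "DxM", 20, 15),
    ("DM-9-17", "DxM", 20, 15),
    ("DM-9-2", "DxM", 20, 14),
    ("DM-9-26", "DxM", 20, 14),
    ("DM-9-14", "DxM", 20, 13),
    ("DM-9-10", "DxM", 20, 10),
    ("DM-9-6", "DxM", 20, 9),
    ("DM-9-15", "DxM", 20, 8),
    ("DM-9-1", "DxM", 20, 8),
    ("DM-9-3", "DxM", 20, 8),
    ("MD-19", "DxM", 20, 6),
    ("MD-102", "MxD", 20, 17),
    ("MD-65", "MxD", 20, 15),
    ("MD-66", "MxD", 20, 15),
    ("MD-64", "MxD", 20, 14),
    ("MD-61", "MxD", 20, 13),
    ("MD-46", "MxD", 20, 13),
    ("MD-19", "MxD", 20, 12),
]


def load_survival_reference() -> list[SurvivalRecord]:
    """Cutting-survival counts of the 23 candidate clones."""
    return [SurvivalRecord(*row) for row in _SURVIVAL]


# early age -> (DxM Rp, DxM stars, MxD Rp, MxD stars); DBH against the
# late-maturity reference age (14 years), correlations across clones.
_AGE_AGE = [
    (2, 0.48, "ns", 0.09, "ns"),
    (3, 0.65, "*", 0.48, "*"),
    (4, 0.58, "*", 0.61, "*"),
    (5, 0.69, "*", 0.71, "*"),
    (6, 0.79, "*", 0.77, "*"),
    (7, 0.88, "**", 0.85, "*"),
    (8, 0.89, "**", 0.87, "*"),
    (9, 0.93, "**", 0.86, "*"),
    (10, 0.96, "**", 0.95, "**"),
    (11, 0.99, "**", 0.98, "**"),
    (12, 0.99, "**", 0.98, "**"),
    (13, 1.00, "**", 0.99, "**"),
]


def load_age_age_reference() -> pd.DataFrame:
    """Published DBH age-age correlations (late reference age 14).

    Long format: one row per cross_type x early_age with the printed
    correlation coefficient and its significance stars.
    """
    rows = []
    for age, r_dm, s_dm, r_md, s_md in _AGE_AGE:
        rows.append({"cross_type": "DxM", "early_age": age, "late_age": 14,
                     "r": r_dm, "stars": s_dm})
        rows.append({"cross_type": "MxD", "early_age": age, "late_age": 14,
                     "r": r_md, "stars": s_md})
    return pd.DataFrame(rows)


# group/clone, cross_type, DBH cm, height m, volume m^3, HDR at mature age
_MATURE = [
    ("DxM population", "DxM", 35, 25, 1.0, 0.71),
    ("DM-9-17", "DxM", 42, 26, 1.4, 0.62),
    ("DM-9-18", "DxM", 39, 26, 1.2, 0.65),
    ("DM-9-14", "DxM", 39, 25, 1.2, 0.63),
    ("MxD population", "MxD", 32, 24, 0.8, 0.75),
    ("MD-61", "MxD", 38, 24, 1.2, 0.63),
]


def load_mature_traits_reference() -> pd.DataFrame:
    """Mature-age trait means of the two populations and the four selected clones."""
    return pd.DataFrame(
        _MATURE, columns=["entry", "cross_type", "dbh_cm", "height_m", "volume_m3", "hdr"]
    )


# clone, quantitative maturity age (NaN = not reached by age 18), volume m^3
_QMA = [
    ("DM-9-22", 12, 0.7), ("DM-9-16", 12, 0.6), ("DM-9-18", 13, 1.0),
    ("DM-9-24", 13, 0.8), ("MD-19", 13, 0.7), ("DM-9-8", 13, 0.6),
    ("MD-102", 13, 0.6), ("DM-9-25", 13, 0.5), ("DM-9-17", 14, 1.2),
    ("DM-9-2", 14, 0.9), ("DM-9-26", 14, 0.8), ("MD-65", 14, 0.6),
    ("DM-9-14", 15, 1.1), ("MD-66", 15, 0.7), ("MD-64", 15, 0.7),
    ("MD-61", 16, 1.1), ("MD-46", np.nan, 0.7),
]


def load_qma_reference() -> pd.DataFrame:
    """Published per-clone quantitative maturity ages and volumes."""
    return pd.DataFrame(_QMA, columns=["clone_id", "qma_age", "volume_at_qma"])
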