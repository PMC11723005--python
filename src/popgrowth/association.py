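"""Correlation, per-age population comparison, and path analysis.

Path analysis decomposes the correlation of each predictor trait
(DBH, height, HDR) with stem volume into a *direct path coefficient*
(DPC) — the standardized partial regression coefficient
``B_i * S_i / S_y`` — and *indirect path coefficients* (IPC) routed
through the other predictors, ``IPC_ij = r_ij * DPC_j``.  The package
reports the total indirect effect ``IPC_i = sum_{j != i} r_ij *
DPC_j`` (per-mediator terms are kept as diagnostics).  On any finite
sample the path identity

    DPC_i + IPC_i = r(trait_i, volume)

holds to numerical precision; it is asserted throughout the test
suite.

Significance stars follow the two-level convention: ``*`` for
p < 0.05, ``**`` for p < 0.01, ``ns`` otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .growth_data import TraitTable

__all__ = [
    "CorrelationResult",
    "PopulationComparison",
    "PathAnalysis",
    "pearson",
    "path_decomposition",
    "windowed_path_analysis",
    "population_anova",
    "DEFAULT_WINDOWS",
    "stars_for",
]

DEFAULT_WINDOWS = ((2, 3), (4, 6), (7, 9), (10, 12), (13, 15), (16, 18))
PATH_PREDICTORS = ("dbh_cm", "height_m", "hdr")


def stars_for(p: float) -> str:
    """Two-level significance stars: ** p<0.01, * p<0.05, else ns."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_value: float
    stars: str


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a Student-t test.

    Missing entries are removed pairwise.  The two-sided p-value uses
    t = r sqrt(n-2) / sqrt(1-r^2) against Student-t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: constant input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exact collinearity up to rounding
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = 2 * st.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_value=float(p), stars=stars_for(p))


@dataclass
class PathResult:
    """Direct/indirect decomposition for one sample (one age window)."""

    predictors: list[str]
    n: int
    dpc: dict[str, float]
    ipc: dict[str, float]
    #: per-mediator indirect terms: ipc_components[i][j] = r_ij * dpc_j
    ipc_components: dict[str, dict[str, float]]
    r_with_response: dict[str, float]
    p_values: dict[str, float]
    stars: dict[str, str]
    window: str | None = None
    cross_type: str | None = None

    def as_rows(self) -> list[dict]:
        return [
            {
                "cross_type": self.cross_type,
                "window": self.window,
                "trait": name,
                "dpc": self.dpc[name],
                "ipc": self.ipc[name],
                "r_with_volume": self.r_with_response[name],
                "p_value": self.p_values[name],
                "stars": self.stars[name],
                "n": self.n,
            }
            for name in self.predictors
        ]


class PathAnalysis(BaseEstimator):
    """Path-coefficient decomposition of a response onto predictors.

    Ordinary least squares (with intercept) gives the partial
    regression coefficients ``B_i``; standardization by trait
    standard deviations yields the direct path coefficients, and the
    predictor correlation matrix routes the indirect ones.
    Coefficient p-values come from the OLS t-tests.

    Attributes (after ``fit``)
    --------------------------
    names_, coef_, dpc_, ipc_, ipc_components_, r_y_, p_values_,
    stars_, n_ — see :class:`PathResult` for meanings.
    """

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        yv = np.asarray(y, dtype=float)
        keep = ~(np.isnan(Xv).any(axis=1) | np.isnan(yv))
        Xv, yv = Xv[keep], yv[keep]
        n, p = Xv.shape
        if n <= p + 1:
            raise ValueError(f"need n > {p + 1} observations, got {n}")

        R = np.corrcoef(Xv, rowvar=False)
        if np.linalg.matrix_rank(R, tol=1e-10) < p:
            collinear = [
                f"{names[i]}~{names[j]}"
                for i in range(p)
                for j in range(i + 1, p)
                if abs(R[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"singular predictor matrix; collinear: {collinear or names}")

        ols = sm.OLS(yv, sm.add_constant(Xv)).fit()
        B = ols.params[1:]
        pvals = ols.pvalues[1:]
        s_x = Xv.std(axis=0, ddof=1)
        s_y = yv.std(ddof=1)

        dpc = B * s_x / s_y
        ipc_comp = {
            names[i]: {names[j]: float(R[i, j] * dpc[j]) for j in range(p) if j != i}
            for i in range(p)
        }
        ipc = {ni: sum(terms.values()) for ni, terms in ipc_comp.items()}
        r_y = {
            names[i]: float(np.corrcoef(Xv[:, i], yv)[0, 1]) for i in range(p)
        }

        self.names_ = names
        self.n_ = n
        self.coef_ = dict(zip(names, B.tolist()))
        self.dpc_ = dict(zip(names, dpc.tolist()))
        self.ipc_ = ipc
        self.ipc_components_ = ipc_comp
        self.r_y_ = r_y
        self.p_values_ = dict(zip(names, pvals.tolist()))
        self.stars_ = {k: stars_for(v) for k, v in self.p_values_.items()}
        return self

    def result(self, window: str | None = None, cross_type: str | None = None) -> PathResult:
        return PathResult(
            predictors=self.names_,
            n=self.n_,
            dpc=self.dpc_,
            ipc=self.ipc_,
            ipc_components=self.ipc_components_,
            r_with_response=self.r_y_,
            p_values=self.p_values_,
            stars=self.stars_,
            window=window,
            cross_type=cross_type,
        )


def path_decomposition(X, y, window: str | None = None, cross_type: str | None = None) -> PathResult:
    """Functional wrapper over :class:`PathAnalysis`."""
    return PathAnalysis().fit(X, y).result(window=window, cross_type=cross_type)


def windowed_path_analysis(
    table: TraitTable,
    windows=DEFAULT_WINDOWS,
    predictors=PATH_PREDICTORS,
    response: str = "volume_m3",
) -> pd.DataFrame:
    """Path analysis per cross type over pooled age windows.

    Observations are pooled tree x year within each window and cross
    type.  Returns a tidy frame with one row per cross_type x window
    x trait.  Empty windows are skipped with a warning.
    """
    if not table.has_traits:
        raise ValueError("traits not derived; call derive_traits first")
    rows: list[dict] = []
    for cross, sub in table.data.groupby("cross_type"):
        for lo, hi in windows:
            label = f"{lo}-{hi}"
            win = sub[(sub["age"] >= lo) & (sub["age"] <= hi)]
            if win.empty:
                warnings.warn(f"{cross} {label}: empty window, skipped", stacklevel=2)
                continue
            res = path_decomposition(
                win[list(predictors)], win[response], window=label, cross_type=str(cross)
            )
            rows.extend(res.as_rows())
    return pd.DataFrame(rows)


@dataclass
class PopulationComparison:
    age: int
    trait: str
    f_stat: float
    p_value: float
    stars: str
    flag: str = "OK"


def population_anova(table: TraitTable, trait: str, age: int) -> PopulationComparison:
    """One-way ANOVA comparing the two cross-type populations at an age.

    Tree-level values are the unit.  With two groups, F equals the
    square of the pooled two-sample t statistic (asserted in tests).
    Identical groups with zero within-group variance but different
    means give F = inf, p = 0 and a ``DEGENERATE`` flag.
    """
    sub = table.data[table.data["age"] == age]
    groups = [g[trait].dropna().to_numpy() for _, g in sub.groupby("cross_type")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError(f"group missing: need both cross types with n >= 2 at age {age}")
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within_ss == 0:
        if np.ptp(means) == 0:
            return PopulationComparison(age, trait, 0.0, 1.0, "ns")
        return PopulationComparison(age, trait, np.inf, 0.0, "**", flag="DEGENERATE")
    f, p = st.f_oneway(*groups)
    return PopulationComparison(age, trait, float(f), float(p), stars_for(float(p)))
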