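"""Synthetic clonal progeny-trial generator.

Simulates the kind of trial the analysis modules expect: two
reciprocal hybrid populations (direct cross ``DxM``, reciprocal
``MxD``) of vegetatively propagated clones planted in a randomized
block design and measured annually for DBH and height.

Growth model
------------
Each cross type has a mean three-parameter logistic curve for DBH and
for height,

    L(t) = K / (1 + exp(-r (t - t0))),

with asymptote ``K``, rate ``r`` and inflection age ``t0``.  Clone
effects are drawn once per clone: a multiplicative log-normal factor
on ``K`` (stable clone ranking, which is what makes late age-age
correlations high) and an additive normal shift on ``t0`` (early/late
developers).  Per-tree, per-year measurement noise is additive
Gaussian, truncated just above zero.  Mortality is Bernoulli per
tree-year; a dead tree's series is truncated at death.

Stem volume is *not* simulated directly: it emerges through the fixed
form-factor volume equation applied to the simulated DBH and height,
which guarantees the sigmoid volume trajectory and lets the
analytic quantitative-maturity age (QMA) of the noise-free curve
serve as a ground-truth oracle for the detector.

All randomness flows from one root ``numpy`` generator seeded by
``seed``.  Stream order is fixed: clone effects first (DxM clones,
then MxD, in id order; per clone: DBH asymptote factor, height
asymptote factor, midpoint shift), then per-tree noise and mortality
in table order.  The same seed therefore yields a byte-identical
table.

Default parameters are calibrated once to the scale of a mature
17-clone poplar trial (final-age population means near 35 cm DBH /
25 m height for the direct cross, slightly lower for the reciprocal;
noise-free QMA inside 12-16 years) and then frozen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .growth_data import DEFAULT_FORM_FACTOR, TraitTable, stem_volume, table_from_frame

__all__ = [
    "LogisticCurve",
    "CrossCurves",
    "GrowthSimConfig",
    "SimTruth",
    "simulate_trial",
    "analytic_qma",
]


class LogisticCurve(BaseModel):
    """Three-parameter logistic growth curve."""

    asymptote: float = Field(gt=0)
    rate: float = Field(gt=0)
    midpoint: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.asymptote / (1.0 + np.exp(-self.rate * (t - self.midpoint)))


class CrossCurves(BaseModel):
    """Mean DBH (cm) and height (m) curves for one cross type."""

    dbh: LogisticCurve
    height: LogisticCurve


def _default_curves() -> dict[str, CrossCurves]:
    # Direct-cross curves sit above the reciprocal in DBH/height
    # (asymptotes), while the reciprocal's faster early height growth
    # gives it the higher juvenile HDR.
    return {
        "DxM": CrossCurves(
            dbh=LogisticCurve(asymptote=36.0, rate=0.42, midpoint=7.0),
            height=LogisticCurve(asymptote=25.5, rate=0.50, midpoint=5.5),
        ),
        "MxD": CrossCurves(
            dbh=LogisticCurve(asymptote=33.0, rate=0.38, midpoint=7.8),
            height=LogisticCurve(asymptote=24.5, rate=0.55, midpoint=5.0),
        ),
    }


class GrowthSimConfig(BaseModel):
    """Configuration of the simulated trial.

    Defaults mirror the reference design: 10 direct-cross and 7
    reciprocal-cross clones, 3+3+2 ramets across three blocks, annual
    measurements from age 2 to age 18.
    """

    n_clones: dict[str, int] = Field(default_factory=lambda: {"DxM": 10, "MxD": 7})
    trees_per_block: tuple[int, ...] = (3, 3, 2)
    age_start: int = 2
    age_end: int = 18
    curves: dict[str, CrossCurves] = Field(default_factory=_default_curves)
    #: coefficient of variation of the per-clone multiplicative asymptote factor
    clone_asymptote_cv_dbh: float = Field(default=0.12, ge=0)
    clone_asymptote_cv_height: float = Field(default=0.06, ge=0)
    #: sd (years) of the per-clone additive midpoint shift (shared by both traits)
    clone_midpoint_sd: float = Field(default=0.8, ge=0)
    noise_sd_dbh: float = Field(default=0.4, ge=0)
    noise_sd_height: float = Field(default=0.3, ge=0)
    annual_mortality: float = Field(default=0.02, ge=0, le=1)
    form_factor: float = Field(default=DEFAULT_FORM_FACTOR, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GrowthSimConfig":
        if self.age_start < 1 or self.age_end <= self.age_start:
            raise ValueError("ages must satisfy 1 <= age_start < age_end")
        if set(self.n_clones) != set(self.curves):
            raise ValueError("n_clones and curves must name the same cross types")
        if any(n < 1 for n in self.n_clones.values()):
            raise ValueError("n_clones values must be >= 1")
        if not self.trees_per_block or any(n < 0 for n in self.trees_per_block):
            raise ValueError("trees_per_block must be non-negative counts")
        return self

    @property
    def ages(self) -> range:
        return range(self.age_start, self.age_end + 1)


@dataclass
class CloneTruth:
    """Realized (noise-free) curve parameters for one clone."""

    clone_id: str
    cross_type: str
    dbh: LogisticCurve
    height: LogisticCurve


@dataclass
class SimTruth:
    """Ground truth of a simulated trial: per-clone noise-free curves."""

    clones: dict[str, CloneTruth]
    config: GrowthSimConfig

    def volume_curve(self, clone_id: str):
        """Noise-free stem volume V(t) of a clone, callable on floats."""
        ct = self.clones[clone_id]
        ff = self.config.form_factor

        def v(t):
            return stem_volume(ct.dbh(t), ct.height(t), ff)

        return v

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.model_dump(),
            "clones": {
                cid: {
                    "cross_type": ct.cross_type,
                    "dbh": ct.dbh.model_dump(),
                    "height": ct.height.model_dump(),
                }
                for cid, ct in self.clones.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        config = GrowthSimConfig(**payload["config"])
        clones = {
            cid: CloneTruth(
                clone_id=cid,
                cross_type=d["cross_type"],
                dbh=LogisticCurve(**d["dbh"]),
                height=LogisticCurve(**d["height"]),
            )
            for cid, d in payload["clones"].items()
        }
        return cls(clones=clones, config=config)


def _clone_ids(config: GrowthSimConfig) -> Iterator[tuple[str, str]]:
    prefix = {"DxM": "DM", "MxD": "MD"}
    for cross in sorted(config.n_clones):
        for i in range(config.n_clones[cross]):
            yield f"{prefix.get(cross, cross)}-{i + 1:02d}", cross


def simulate_trial(config: GrowthSimConfig | None = None) -> tuple[TraitTable, SimTruth]:
    """Simulate a full trial; returns the raw measurement table and truth.

    The returned :class:`~popgrowth.growth_data.TraitTable` is raw
    (no derived traits); run it through ``derive_traits`` as you would
    a real table.
    """
    config = config or GrowthSimConfig()
    rng = np.random.default_rng(config.seed)

    clones: dict[str, CloneTruth] = {}
    for clone_id, cross in _clone_ids(config):
        base = config.curves[cross]
        k_dbh = math.exp(rng.normal(0.0, config.clone_asymptote_cv_dbh))
        k_h = math.exp(rng.normal(0.0, config.clone_asymptote_cv_height))
        dt0 = rng.normal(0.0, config.clone_midpoint_sd)
        clones[clone_id] = CloneTruth(
            clone_id=clone_id,
            cross_type=cross,
            dbh=LogisticCurve(
                asymptote=base.dbh.asymptote * k_dbh,
                rate=base.dbh.rate,
                midpoint=base.dbh.midpoint + dt0,
            ),
            height=LogisticCurve(
                asymptote=base.height.asymptote * k_h,
                rate=base.height.rate,
                midpoint=base.height.midpoint + dt0,
            ),
        )

    ages = np.array(list(config.ages))
    rows = []
    for clone_id, ct in clones.items():
        dbh_true = ct.dbh(ages)
        h_true = ct.height(ages)
        for block, n_trees in enumerate(config.trees_per_block, start=1):
            for tree in range(1, n_trees + 1):
                tree_id = f"t{tree}"
                # death year drawn up front so the noise stream per tree
                # has fixed length regardless of survival
                alive_mask = rng.random(len(ages)) >= config.annual_mortality
                dbh_noise = rng.normal(0.0, config.noise_sd_dbh, len(ages))
                h_noise = rng.normal(0.0, config.noise_sd_height, len(ages))
                for j, age in enumerate(ages):
                    if not alive_mask[j]:
                        break  # tree dies; series truncated at death
                    dbh = max(dbh_true[j] + dbh_noise[j], 0.05)
                    height = max(h_true[j] + h_noise[j], 0.05)
                    rows.append(
                        (clone_id, ct.cross_type, block, tree_id, int(age), dbh, height)
                    )

    df = pd.DataFrame(
        rows,
        columns=["clone_id", "cross_type", "block", "tree_id", "age", "dbh_cm", "height_m"],
    )
    table = table_from_frame(df, source=f"simulate_trial(seed={config.seed})")
    return table, SimTruth(clones=clones, config=config)


def analytic_qma(
    truth: SimTruth,
    clone_id: str,
    grid_step: float = 0.01,
    tol: float = 1e-8,
) -> float:
    """Real-valued quantitative-maturity age of a clone's noise-free curve.

    QMA is the age where the mean annual increment MAI(t) = V(t)/t
    equals the one-year periodic annual increment PAI(t) = V(t) -
    V(t-1), located by a dense grid scan followed by bisection.  The
    crossing must be preceded by an exceedance (PAI > MAI), so a
    series that is already declining at the first measurable age does
    not get a spurious maturity age.  Returns ``nan`` if no crossing
    occurs in the simulated age range ("not reached").
    """
    if clone_id not in truth.clones:
        raise KeyError(clone_id)
    v = truth.volume_curve(clone_id)
    lo = truth.config.age_start + 1  # PAI needs a one-year lookback
    hi = truth.config.age_end

    def diff(t):
        return (v(t) - v(t - 1.0)) - v(t) / t

    ts = np.arange(lo, hi + grid_step / 2, grid_step)
    d = diff(ts)
    exceeded = False
    for i in range(1, len(ts)):
        if d[i - 1] > 0:
            exceeded = True
        if exceeded and d[i] <= 0 <= d[i - 1]:
            a, b = ts[i - 1], ts[i]
            while b - a > tol:
                m = 0.5 * (a + b)
                if diff(m) > 0:
                    a = m
                else:
                    b = m
            return float(0.5 * (a + b))
    return float("nan")
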