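"""End-to-end orchestration: simulate -> traits -> QMA -> path -> ESE -> select.

One call runs every analysis stage in order on a simulated trial (or
a caller-supplied measurement table) and returns the intermediate
products, so the command line, the test suite and reproduction
scripts all execute the same code path.
"""

from __future__ import annotations

from typing import Any

from .growth_data import TraitTable, derive_traits
from .synthetic_data import GrowthSimConfig, SimTruth, simulate_trial
from .increment_qma import qma_table
from .association import windowed_path_analysis
from .early_selection import age_age_table, optimal_window
from .selection_pipeline import select_top_clones, volume_cv

__all__ = ["run_pipeline"]


def run_pipeline(
    seed: int = 0,
    config: GrowthSimConfig | None = None,
    table: TraitTable | None = None,
    late_age: int = 14,
    selection_rate: float = 0.25,
) -> dict[str, Any]:
    """Run the full analysis chain and return every stage's output.

    If ``table`` is None a trial is simulated from ``config`` (or the
    default configuration) with ``seed``.  Returns a dict with keys
    ``traits`` (derived TraitTable), ``truth`` (SimTruth or None),
    ``qma`` (per-clone maturity frame), ``path`` (windowed path
    coefficients), ``age_age`` (age-age correlation/ESE rows),
    ``window`` (optimal early-selection window), ``selection``
    (selection report dict) and ``cv`` (population volume CV frame).
    """
    truth: SimTruth | None = None
    if table is None:
        cfg = (config or GrowthSimConfig()).model_copy(update={"seed": seed})
        table, truth = simulate_trial(cfg)
    traits = table if table.has_traits else derive_traits(table)

    age_age = age_age_table(traits, late_age=late_age)
    return {
        "traits": traits,
        "truth": truth,
        "qma": qma_table(traits),
        "path": windowed_path_analysis(traits),
        "age_age": age_age,
        "window": optimal_window(age_age),
        "selection": select_top_clones(traits, rate=selection_rate),
        "cv": volume_cv(traits, level="cross_type"),
    }
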