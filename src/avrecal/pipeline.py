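"""End-to-end orchestration: simulate a study, analyze a trial table."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import model_selection, shift_analysis, weighted_model
from .experiment_design import DesignConfig, build_schedule
from .synthetic_observer import ObserverParams, simulate_experiment


def simulate_study(
    design: DesignConfig | None = None,
    observer: ObserverParams | None = None,
    n_subjects: int = 11,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Schedule plus simulated responses for a whole cohort."""
    design = design or DesignConfig()
    observer = observer or ObserverParams()
    if rng is None:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    schedule = build_schedule(design, n_subjects, rng)
    return simulate_experiment(schedule, observer, rng)


def analyze_table(
    table: pd.DataFrame,
    candidates: Sequence[Sequence[str]] = model_selection.DEFAULT_CANDIDATES,
    n_blocks: int = 4,
    fit_set: Sequence[str] = ("SQ5", "D"),
) -> dict:
    """Run the full analysis chain on a completed trial table.

    Returns a dict with the condition summaries, the 32-type shift
    vector, the by-position conditional tables, the time-block ANOVA,
    the property/shift correlation screen, the candidate comparison
    (or a degeneracy flag when a candidate fits perfectly), and the
    weights of ``fit_set``.
    """
    shifts = shift_analysis.shifts_by_sequence_type(table)
    out: dict = {
        "condition_summaries": shift_analysis.condition_summaries(table),
        "shift_vector": shifts,
        "conditional_by_position": shift_analysis.conditional_shift_by_position(table),
        "single_discrepant": shift_analysis.single_discrepant_summary(table),
        "block_anova": shift_analysis.block_time_course(table, n_blocks),
        "correlations": shift_analysis.property_shift_correlations(shifts),
        "fit": weighted_model.fit_properties(shifts, tuple(fit_set)),
    }
    try:
        comparison = model_selection.compare_models(shifts, candidates)
        out["model_comparison"] = comparison
        out["selected"] = comparison.loc[comparison["selected"], "properties"].iloc[0]
    except model_selection.PerfectFitError as exc:
        out["model_comparison"] = None
        out["selected"] = None
        out["degenerate_fit"] = str(exc)
    return out
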