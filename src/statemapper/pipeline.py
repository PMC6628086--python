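"""End-to-end orchestration of the grid sweep, cleaning and statistics.

One call runs: grid sweep per condition -> missing-return cleaning ->
condition intersection -> correlation table -> parameter selection ->
subject-table fill -> paired comparison -> Models 1 and 2. Per-stage counts
(subjects in/out, missing-cell tallies) are logged at INFO so the cleaning
is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .grid import (
    build_subject_table,
    correlation_table,
    impute_and_exclude,
    intersect_conditions,
    run_grid,
    select_parameters,
)
from .mapper import GridPoint, StateSeries
from .stats import (
    ModelComparison,
    PairedTestResult,
    RegressionResult,
    compare_models,
    fit_model,
    paired_condition_test,
)

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    grid: list[GridPoint]
    raw_results: dict[str, pd.DataFrame]  # condition -> subjects x grid returns
    cleaned_results: dict[str, pd.DataFrame]
    excluded: dict[str, list[str]]
    correlations: pd.DataFrame
    selected: dict[str, GridPoint]
    subject_table: pd.DataFrame
    paired: PairedTestResult
    fits: dict[tuple[str, int], RegressionResult]
    comparisons: dict[str, ModelComparison]


def run_pipeline(
    series: Mapping[tuple[str, str], StateSeries],
    behavioral: pd.DataFrame,
    grid: Sequence[GridPoint],
    early_window_end: int = 32,
    selection_mode: str = "pooled",
) -> PipelineResult:
    """Run the full analysis on a two-condition cohort.

    ``series`` maps (subject, condition) to recordings; ``behavioral`` holds
    the per-subject reaction times and accuracies. Returns every intermediate
    product along with the final statistics.
    """
    raw: dict[str, pd.DataFrame] = {}
    cleaned: dict[str, pd.DataFrame] = {}
    excluded: dict[str, list[str]] = {}
    for cond in ("0B", "2B"):
        cond_series = {s: v for (s, c), v in series.items() if c == cond}
        res = run_grid(cond_series, grid, early_window_end)
        raw[cond] = res
        n_missing = int(res.isna().sum().sum())
        log.info(
            "%s: %d subjects x %d grid points, %d missing return points",
            cond, res.shape[0], res.shape[1], n_missing,
        )
        cleaned[cond], excluded[cond] = impute_and_exclude(res)
        log.info(
            "%s: excluded %d subjects (missing at >= half the grid), kept %d",
            cond, len(excluded[cond]), cleaned[cond].shape[0],
        )

    skeleton = intersect_conditions(cleaned["0B"], cleaned["2B"], behavioral)
    log.info("intersection: %d subjects in both conditions", skeleton.shape[0])

    corr = correlation_table(
        cleaned["0B"], cleaned["2B"], behavioral, skeleton["Subject"]
    )
    if selection_mode == "pooled":
        gp = select_parameters(corr, mode="pooled")
        selected = {"0B": gp, "2B": gp}
    else:
        selected = {
            c: select_parameters(corr, mode="per-condition", condition=c)
            for c in ("0B", "2B")
        }
    log.info("selected parameters: 0B %s, 2B %s",
             selected["0B"].label, selected["2B"].label)

    table = build_subject_table(
        skeleton, cleaned["0B"], cleaned["2B"], selected["0B"], selected["2B"]
    )
    paired = paired_condition_test(table)
    fits = {
        (cond, m): fit_model(table, cond, m)
        for cond in ("0B", "2B")
        for m in (1, 2)
    }
    comparisons = {
        cond: compare_models(fits[(cond, 1)], fits[(cond, 2)]) for cond in ("0B", "2B")
    }
    return PipelineResult(
        list(grid), raw, cleaned, excluded, corr, selected, table, paired,
        fits, comparisons,
    )
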