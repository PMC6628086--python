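"""Parameter-grid sweep, cohort cleaning and Mapper parameter selection.

The Mapper pipeline is run at every point of a grid G of (Int, Ovr, Bin)
parameter triples, recording the return-point marker per subject, condition
and grid point. Cleaning follows two rules: a subject missing the marker at
at least half of the grid points is excluded for that condition; remaining
missing cells are imputed with the mean of the subject's present cells.
Subjects must survive cleaning in both conditions and carry complete
behavioral data. Parameters are then selected by the strength of the
(negative) Pearson correlation between return points and accuracy.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_EARLY_WINDOW_END, detect_return_point
from .mapper import GridPoint, StateSeries, run_mapper

__all__ = [
    "DEFAULT_INT_SET",
    "DEFAULT_OVR_SET",
    "DEFAULT_BIN_SET",
    "EmptyCohortError",
    "enumerate_grid",
    "run_grid",
    "impute_and_exclude",
    "intersect_conditions",
    "correlation_table",
    "select_parameters",
    "build_subject_table",
    "SUBJECT_TABLE_COLUMNS",
]

DEFAULT_INT_SET = (5, 6, 7)
DEFAULT_OVR_SET = (50, 60, 70)
DEFAULT_BIN_SET = (5, 10)

SUBJECT_TABLE_COLUMNS = [
    "Subject",
    "Mapper0B",
    "Mapper2B",
    "0B Median Reaction",
    "2B Median Reaction",
    "0BAccuracy",
    "2BAccuracy",
]


class EmptyCohortError(RuntimeError):
    """No subject survives cleaning/intersection."""


def enumerate_grid(
    int_set: Iterable[int] = DEFAULT_INT_SET,
    ovr_set: Iterable[float] = DEFAULT_OVR_SET,
    bin_set: Iterable[int] = DEFAULT_BIN_SET,
) -> list[GridPoint]:
    """Cartesian product of the parameter sets, in (Int, Ovr, Bin) lexicographic order."""
    ints, ovrs, bins = sorted(set(int_set)), sorted(set(ovr_set)), sorted(set(bin_set))
    if not (ints and ovrs and bins):
        raise ValueError("all parameter sets must be nonempty")
    return [GridPoint(i, o, b) for i, o, b in itertools.product(ints, ovrs, bins)]


def run_grid(
    series_map: Mapping[str, StateSeries],
    grid: Sequence[GridPoint],
    early_window_end: int = DEFAULT_EARLY_WINDOW_END,
) -> pd.DataFrame:
    """Return-point matrix: one row per subject, one column per grid point.

    Cell (s, g) is the return point of subject s's Mapper graph at grid
    point g, or NaN when the marker is missing. Cells are independent of one
    another (the sweep is embarrassingly parallel); this implementation
    evaluates them serially and deterministically.
    """
    subjects = list(series_map)
    data = np.full((len(subjects), len(grid)), np.nan)
    for i, subj in enumerate(subjects):
        series = series_map[subj]
        for j, gp in enumerate(grid):
            graph = run_mapper(series, gp)
            rp = detect_return_point(graph, early_window_end)
            if rp.value is not None:
                data[i, j] = rp.value
    return pd.DataFrame(data, index=subjects, columns=[gp.label for gp in grid])


def impute_and_exclude(result: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Apply the missing-return-point cleaning rules.

    A subject with missing values at >= ceil(|G| / 2) grid points is dropped;
    any remaining missing cell is replaced by the mean of that subject's
    present cells (kept fractional). Returns the cleaned matrix and the
    excluded subject ids.
    """
    n_grid = result.shape[1]
    if n_grid < 1:
        raise ValueError("need at least one grid point")
    threshold = math.ceil(n_grid / 2)
    n_missing = result.isna().sum(axis=1)
    excluded = list(result.index[n_missing >= threshold])
    kept = result.drop(index=excluded)
    cleaned = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    return cleaned, excluded


def intersect_conditions(
    result_0b: pd.DataFrame,
    result_2b: pd.DataFrame,
    behavioral: pd.DataFrame,
) -> pd.DataFrame:
    """Subjects surviving cleaning in both conditions with complete behavior.

    Returns the skeleton of the cleaned seven-column dataset: Subject plus
    the behavioral columns; the Mapper0B/Mapper2B columns are filled later
    once parameters are selected. Raises EmptyCohortError when no subject
    qualifies.
    """
    behav = behavioral.set_index("Subject")
    needed = ["0B Median Reaction", "2B Median Reaction", "0BAccuracy", "2BAccuracy"]
    complete = behav.index[behav[needed].notna().all(axis=1)]
    common = [
        s for s in result_0b.index if s in set(result_2b.index) and s in set(complete)
    ]
    if not common:
        raise EmptyCohortError("no subject survives cleaning in both conditions")
    skeleton = behav.loc[common, needed].reset_index()
    return skeleton[["Subject", *needed]]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_table(
    result_0b: pd.DataFrame,
    result_2b: pd.DataFrame,
    behavioral: pd.DataFrame,
    subjects: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson r between return points and accuracy, per grid point and condition.

    Rows are grid-point labels; columns '0B', '2B' and their per-grid-point
    'mean'. A zero-variance column yields NaN and is excluded from the mean.
    Restricting to ``subjects`` (typically the intersected cohort) keeps both
    conditions on the same sample.
    """
    behav = behavioral.set_index("Subject")
    if subjects is None:
        subjects = [s for s in result_0b.index if s in set(result_2b.index)]
    subjects = list(subjects)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    rows = {}
    for label in result_0b.columns:
        r0 = _pearson(
            result_0b.loc[subjects, label], behav.loc[subjects, "0BAccuracy"]
        )
        r2 = _pearson(
            result_2b.loc[subjects, label], behav.loc[subjects, "2BAccuracy"]
        )
        rows[label] = {"0B": r0, "2B": r2, "mean": np.nanmean([r0, r2])}
    return pd.DataFrame.from_dict(rows, orient="index")[["0B", "2B", "mean"]]


def select_parameters(
    table: pd.DataFrame,
    mode: str = "pooled",
    condition: Optional[str] = None,
    by_magnitude: bool = False,
) -> GridPoint:
    """Grid point with the strongest return-point/accuracy correlation.

    ``mode='per-condition'`` minimizes the chosen condition's r;
    ``mode='pooled'`` minimizes the column-wise mean across conditions (the
    variant used for the 0B-vs-2B comparison). The expected direction is
    negative (longer returns, lower accuracy), so "strongest" means most
    negative; ``by_magnitude=True`` selects by largest |r| instead. Ties
    break toward the earlier grid point in enumeration order.
    """
    if table.empty:
        raise ValueError("correlation table is empty")
    if mode == "pooled":
        col = table["mean"]
    elif mode == "per-condition":
        if condition not in ("0B", "2B"):
            raise ValueError("per-condition mode needs condition '0B' or '2B'")
        col = table[condition]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    scores = -col.abs() if by_magnitude else col
    if scores.isna().all():
        raise ValueError("all correlations undefined; cannot select parameters")
    best = scores.idxmin()  # idxmin keeps the first occurrence on ties
    return GridPoint.from_label(best)


def build_subject_table(
    skeleton: pd.DataFrame,
    result_0b: pd.DataFrame,
    result_2b: pd.DataFrame,
    gp_0b: GridPoint,
    gp_2b: GridPoint,
) -> pd.DataFrame:
    """Fill the Mapper0B/Mapper2B columns at the selected grid points."""
    table = skeleton.copy()
    subjects = table["Subject"]
    table.insert(1, "Mapper0B", result_0b.loc[subjects, gp_0b.label].to_numpy())
    table.insert(2, "Mapper2B", result_2b.loc[subjects, gp_2b.label].to_numpy())
    return table[SUBJECT_TABLE_COLUMNS]
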