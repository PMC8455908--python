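"""Composite score construction for the survey instruments.

Each scale used in the harsh-discipline analysis is a simple aggregate of
item-level responses:

* harsh discipline — sum of the 9 CTSPC items (5 psychological aggression,
  4 physical assault), each rated 0-5 for frequency over the past two weeks;
* father involvement — mean of 20 task-division ratings (1 = almost
  exclusively mother, 5 = almost exclusively father);
* work changes — count of 14 binary negative employment-change indicators;
* general psychopathology — mean of 27 symptom items (BSI-18 without
  suicidality plus a 10-item PTSD checklist subset), each 1-5;
* COVID-19 health concerns — mean of the two distress ratings (self;
  family/friends).

Single-item measures (work stress 1-10, marital conflict 1-6) pass through
unscored.  ``score_dataset`` applies a column manifest to a raw respondent
table and emits one column per composite, with person-mean imputation for
predictor scales with at most 10% missing items and listwise deletion of
records missing any outcome item.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleValidationError",
    "score_harsh_discipline",
    "score_father_involvement",
    "score_work_changes",
    "score_psychopathology",
    "score_health_concerns",
    "cronbach_alpha",
    "score_dataset",
]

N_CTSPC_ITEMS = 9
N_FATHER_ITEMS = 20
N_WORK_FLAGS = 14
N_PSYCHOPATHOLOGY_ITEMS = 27
N_HEALTH_ITEMS = 2

#: fraction of a predictor scale's items that may be missing before the
#: record is dropped instead of person-mean imputed
MAX_MISSING_FRACTION = 0.10


class ScaleValidationError(ValueError):
    """Raised when item responses violate a scale's range or length."""


def _check_items(items: Sequence[float], n: int, lo: float, hi: float,
                 name: str, integer: bool = True) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ScaleValidationError(
            f"{name} requires exactly {n} items, got {arr.size}")
    if np.isnan(arr).any():
        bad = int(np.flatnonzero(np.isnan(arr))[0])
        raise ScaleValidationError(f"{name} item {bad + 1} is missing")
    if integer and not np.all(arr == np.round(arr)):
        bad = int(np.flatnonzero(arr != np.round(arr))[0])
        raise ScaleValidationError(
            f"{name} item {bad + 1} = {arr[bad]} is not an integer")
    out = (arr < lo) | (arr > hi)
    if out.any():
        bad = int(np.flatnonzero(out)[0])
        raise ScaleValidationError(
            f"{name} item {bad + 1} = {arr[bad]} outside [{lo}, {hi}]")
    return arr


def score_harsh_discipline(items: Sequence[int]) -> int:
    """Sum the 9 CTSPC harsh-discipline items (range 0-45)."""
    arr = _check_items(items, N_CTSPC_ITEMS, 0, 5, "CTSPC")
    return int(arr.sum())


def score_father_involvement(items: Sequence[int]) -> float:
    """Mean of the 20 task-division items; higher = more father involvement."""
    arr = _check_items(items, N_FATHER_ITEMS, 1, 5, "father involvement")
    return float(arr.mean())


def score_work_changes(flags: Sequence[int]) -> int:
    """Count of reported negative employment changes (0-14)."""
    arr = _check_items(flags, N_WORK_FLAGS, 0, 1, "work changes")
    return int(arr.sum())


def score_psychopathology(items: Sequence[int]) -> float:
    """Mean of the 27 psychopathology items (1-5)."""
    arr = _check_items(items, N_PSYCHOPATHOLOGY_ITEMS, 1, 5, "psychopathology")
    return float(arr.mean())


def score_health_concerns(items: Sequence[float]) -> float:
    """Mean of the two COVID-19 health-concern distress ratings."""
    arr = _check_items(items, N_HEALTH_ITEMS, 1, 10, "health concerns",
                       integer=False)
    return float(arr.mean())


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total scores),
    with sample (ddof=1) variances over respondents.

    Parameters
    ----------
    item_matrix
        Respondents x items table, at least 3 rows and 2 columns.

    Raises
    ------
    ScaleValidationError
        If the matrix is too small or the total-score variance is zero.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ScaleValidationError(
            "cronbach_alpha needs >=3 respondents and >=2 items, "
            f"got shape {x.shape}")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ScaleValidationError(
            "total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# dataset-level scoring

_SCALES = {
    "harsh_discipline": dict(n=N_CTSPC_ITEMS, lo=0, hi=5, stat="sum",
                             outcome=True),
    "father_involvement": dict(n=N_FATHER_ITEMS, lo=1, hi=5, stat="mean",
                               outcome=False),
    "work_changes": dict(n=N_WORK_FLAGS, lo=0, hi=1, stat="sum",
                         outcome=False),
    "psychopathology": dict(n=N_PSYCHOPATHOLOGY_ITEMS, lo=1, hi=5,
                            stat="mean", outcome=False),
    "health_concerns": dict(n=N_HEALTH_ITEMS, lo=1, hi=10, stat="mean",
                            outcome=False),
}


def score_dataset(data: pd.DataFrame,
                  manifest: Mapping[str, Sequence[str]],
                  passthrough: Sequence[str] = ()) -> pd.DataFrame:
    """Apply a column manifest to a raw respondent table.

    ``manifest`` maps composite names (keys of the known scales) to the raw
    item columns; a composite may instead map to a single pre-scored column,
    which is copied through unchanged.  Records with any missing outcome item
    are dropped; predictor composites with <=10% missing items are person-mean
    imputed, records above that threshold are dropped.

    Returns a scored table with one column per composite plus ``passthrough``
    columns, indexed like the surviving input rows.
    """
    keep = np.ones(len(data), dtype=bool)
    scored: dict[str, np.ndarray] = {}
    for name, cols in manifest.items():
        if name not in _SCALES:
            raise ScaleValidationError(f"unknown composite '{name}'")
        info = _SCALES[name]
        cols = list(cols)
        if len(cols) == 1:  # pre-scored column passes through
            scored[name] = data[cols[0]].to_numpy(dtype=float)
            keep &= ~np.isnan(scored[name])
            continue
        if len(cols) != info["n"]:
            raise ScaleValidationError(
                f"{name} expects {info['n']} item columns, got {len(cols)}")
        items = data[cols].to_numpy(dtype=float)
        out = (items < info["lo"]) | (items > info["hi"])
        if np.nansum(out) > 0:
            r, c = np.argwhere(out & ~np.isnan(items))[0]
            raise ScaleValidationError(
                f"{name} column '{cols[c]}' row {data.index[r]}: value "
                f"{items[r, c]} outside [{info['lo']}, {info['hi']}]")
        missing = np.isnan(items)
        frac = missing.mean(axis=1)
        if info["outcome"]:
            keep &= frac == 0
        else:
            keep &= frac <= MAX_MISSING_FRACTION
            # person-mean imputation from the respondent's answered items
            row_mean = np.nanmean(np.where(missing.all(axis=1)[:, None],
                                           0.0, items), axis=1)
            items = np.where(missing, row_mean[:, None], items)
        scored[name] = (items.sum(axis=1) if info["stat"] == "sum"
                        else items.mean(axis=1))
    out_df = pd.DataFrame(scored, index=data.index)
    for col in passthrough:
        out_df[col] = data[col]
        keep &= ~out_df[col].isna().to_numpy()
    return out_df.loc[keep]
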