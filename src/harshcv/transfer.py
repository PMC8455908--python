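"""Cross-cohort transfer validation of the selected models (step 2).

Each cohort's winning model is cross-validated not only on its own data but
on every other cohort's data, with all candidate models sharing fold plans
within a dataset.  The per-repeat RMSE_p distributions quantify how well a
risk-factor model selected in one country transfers to another; the
per-dataset win percentages summarize which candidate predicts best.

Fold plans for this step are drawn from fresh child seeds, independent of
the step-1 selection folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .cv_engine import evaluate_masks, make_fold_plan, _model_col_sets
from .model_space import ModelSpec, build_full_design

__all__ = ["TransferResult", "cross_validate_models", "plot_tables"]


@dataclass
class TransferResult:
    """RMSE_p distributions of every candidate model on every dataset."""

    datasets: tuple[str, ...]
    candidates: tuple[str, ...]
    #: rmse[dataset][candidate] -> (R,) per-repeat pooled RMSE_p
    rmse: dict[str, dict[str, np.ndarray]] = field(repr=False)
    #: win_percent[dataset][candidate] -> % of repeats won
    win_percent: dict[str, dict[str, float]] = field(default_factory=dict)


def cross_validate_models(datasets: Mapping[str, pd.DataFrame],
                          winners: Mapping[str, ModelSpec],
                          K: int = 10, R: int = 200, seed: int = 0,
                          outcome: str = "harsh_discipline",
                          inverted_folds: bool = False) -> TransferResult:
    """Cross-validate each candidate winning model on every dataset.

    Within a dataset, all candidates share one fold plan (fresh child seed
    per dataset), are trained and tested on identical splits, and the
    candidate with the lowest RMSE_p is recorded as the repeat's winner
    (ties to fewest parameters, then candidate order).

    Raises ``KeyError`` naming the dataset and variable if a winner uses a
    variable absent from any dataset.
    """
    cand_names = list(winners)
    effects = winners[cand_names[0]].effects
    for name, spec in winners.items():
        if spec.effects is not effects and spec.effects != effects:
            raise ValueError("all winning models must share one candidate "
                             "effect set")
    for ds_name, df in datasets.items():
        for cand, spec in winners.items():
            for v in spec.variables:
                if v not in df.columns:
                    raise KeyError(f"dataset '{ds_name}' lacks variable "
                                   f"'{v}' required by model '{cand}'")
    specs = [winners[c] for c in cand_names]
    col_sets = _model_col_sets(specs)
    # precedence for ties: fewest parameters, then candidate order
    prec = sorted(range(len(specs)),
                  key=lambda m: (specs[m].n_params, m))
    child_seeds = np.random.SeedSequence(seed).spawn(len(datasets))
    rmse_out: dict[str, dict[str, np.ndarray]] = {}
    wins_out: dict[str, dict[str, float]] = {}
    for ds_name, child in zip(datasets, child_seeds):
        df = datasets[ds_name]
        X, y, _ = build_full_design(df, effects, outcome=outcome)
        plan = make_fold_plan(len(y), K, R,
                              int(child.generate_state(1)[0] % (2 ** 31)))
        rmse = evaluate_masks(X, y, col_sets, plan,
                              inverted_folds=inverted_folds)
        wins = np.zeros(len(specs), dtype=int)
        for r in range(R):
            row = rmse[r, prec]
            wins[prec[int(np.argmin(row))]] += 1
        rmse_out[ds_name] = {c: rmse[:, m] for m, c in enumerate(cand_names)}
        wins_out[ds_name] = {c: 100.0 * wins[m] / R
                             for m, c in enumerate(cand_names)}
    return TransferResult(datasets=tuple(datasets),
                          candidates=tuple(cand_names),
                          rmse=rmse_out, win_percent=wins_out)


def plot_tables(result: TransferResult,
                density_points: int = 128) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready summaries of the transfer RMSE distributions.

    Returns a quantile table (min, q1, median, q3, max per dataset x
    candidate — the boxplot statistics) and a long-format Gaussian kernel
    density table (Silverman bandwidth) with ``density_points`` grid points
    per distribution.  Degenerate (constant) distributions get a single
    point mass row in the density table.
    """
    if not result.rmse:
        raise ValueError("empty transfer result")
    qrows, drows = [], []
    for ds in result.datasets:
        for cand in result.candidates:
            v = np.asarray(result.rmse[ds][cand], dtype=float)
            qs = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
            qrows.append({"dataset": ds, "model": cand, "min": qs[0],
                          "q1": qs[1], "median": qs[2], "q3": qs[3],
                          "max": qs[4]})
            if np.ptp(v) == 0:
                drows.append({"dataset": ds, "model": cand,
                              "rmse": v[0], "density": np.inf})
                continue
            kde = gaussian_kde(v, bw_method="silverman")
            lo, hi = v.min(), v.max()
            pad = 3 * kde.factor * v.std(ddof=1)
            grid = np.linspace(lo - pad, hi + pad, density_points)
            dens = kde(grid)
            for g, dv in zip(grid, dens):
                drows.append({"dataset": ds, "model": cand,
                              "rmse": g, "density": dv})
    return pd.DataFrame(qrows), pd.DataFrame(drows)
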