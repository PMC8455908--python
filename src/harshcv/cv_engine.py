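"""Repeated K-fold cross-validation with shared folds and win-count selection.

Every candidate model is scored on identical row-to-fold assignments within
a repeat, so differences in prediction error reflect the models, not the
splits.  Per repeat, out-of-fold squared errors are pooled over all K test
folds into a single root mean square error of prediction (RMSE_p); the
repeat's winner is the model with the lowest RMSE_p, ties going to the model
with fewest parameters, then lowest mask.  The run winner is the model that
wins the most repeats.

Fitting ~13k linear models x K folds x R repeats by refitting each design
would be prohibitively slow, so the engine works from sufficient statistics:
per fold it accumulates the Gram matrix X'X, the cross-moment X'y, and y'y
of the *full* candidate design; any model's training normal equations and
test-fold sum of squared errors are then submatrix operations, batched over
all models of equal size with one LAPACK call.  The sufficient-statistics
path is algebraically identical to refitting (verified in the test suite to
1e-8).

The fold orientation is configurable: the standard convention trains on
K-1 folds and tests on the held-out fold; ``inverted_folds=True`` trains on
a single fold and tests on the remaining K-1 (the literal reading of the
original protocol description).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_space import CandidateEffectSet, ModelSpec, build_full_design, enumerate_models

__all__ = [
    "FoldPlan",
    "CVRunResult",
    "make_fold_plan",
    "rmse_prediction",
    "fit_linear_suffstats",
    "evaluate_masks",
    "run_cv_selection",
    "wins_table",
]

#: ridge jitter added to a singular training Gram submatrix before giving up
SINGULAR_JITTER = 1e-10

#: abort threshold: fraction of repeats in which every model failed
MAX_DISCARDED_FRACTION = 0.10


@dataclass(frozen=True)
class FoldPlan:
    """Seeded assignment of rows to K folds for each of R repeats.

    ``assignment[r, i]`` is the fold id (0..K-1) of row ``i`` in repeat
    ``r``.  Fold sizes within a repeat differ by at most one.
    """

    K: int
    R: int
    n: int
    seed: int
    assignment: np.ndarray = field(repr=False)

    def fold_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[repeat] == fold)


def make_fold_plan(n: int, K: int, R: int, seed: int) -> FoldPlan:
    """Random balanced fold assignments, reproducible from ``seed``.

    Requires ``n >= 2K`` so that every training set (in either orientation)
    holds at least two rows per fold.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if R < 1:
        raise ValueError("R must be at least 1")
    if n < 2 * K:
        raise ValueError(f"need n >= 2K rows, got n={n}, K={K}")
    rng = np.random.default_rng(seed)
    base = np.empty(n, dtype=np.int32)
    # fold sizes n//K or n//K + 1 (first n % K folds get the extra row)
    sizes = np.full(K, n // K, dtype=int)
    sizes[: n % K] += 1
    start = 0
    for k, s in enumerate(sizes):
        base[start:start + s] = k
        start += s
    assignment = np.empty((R, n), dtype=np.int32)
    for r in range(R):
        assignment[r] = rng.permutation(base)
    return FoldPlan(K=K, R=R, n=n, seed=seed, assignment=assignment)


def rmse_prediction(observed, predicted) -> float:
    """Root mean square error of prediction."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length "
                         "non-empty vectors")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def fit_linear_suffstats(gram: np.ndarray, cross: np.ndarray,
                         cols) -> np.ndarray | None:
    """Least-squares coefficients for a column subset from X'X and X'y.

    Solves ``gram[cols, cols] beta = cross[cols]``.  A singular submatrix is
    retried with a small ridge jitter on the diagonal (with a warning);
    if still singular, returns ``None`` (the model is treated as failed).
    """
    cols = np.asarray(cols, dtype=int)
    sub = gram[np.ix_(cols, cols)]
    rhs = cross[cols]
    try:
        return np.linalg.solve(sub, rhs)
    except np.linalg.LinAlgError:
        pass
    warnings.warn("singular training Gram submatrix; retrying with "
                  f"diagonal jitter {SINGULAR_JITTER}", UserWarning,
                  stacklevel=2)
    try:
        return np.linalg.solve(sub + SINGULAR_JITTER * np.eye(len(cols)), rhs)
    except np.linalg.LinAlgError:
        return None


def _group_by_size(col_sets: list[np.ndarray]) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Group model column sets by size -> (model indices, stacked index array)."""
    buckets: dict[int, list[int]] = defaultdict(list)
    for m, cols in enumerate(col_sets):
        buckets[len(cols)].append(m)
    out = {}
    for p, members in buckets.items():
        idx = np.stack([col_sets[m] for m in members])
        out[p] = (np.asarray(members), idx)
    return out


def evaluate_masks(X: np.ndarray, y: np.ndarray, col_sets: list[np.ndarray],
                   plan: FoldPlan, inverted_folds: bool = False) -> np.ndarray:
    """Per-repeat pooled RMSE_p for each model, from sufficient statistics.

    Parameters
    ----------
    X, y
        Full candidate design (intercept in column 0) and response; rows
        must match ``plan.n``.
    col_sets
        One integer column-index array per model (each including column 0).
    plan
        Shared fold plan; all models see identical splits.

    Returns
    -------
    ndarray of shape (R, M); entries are ``inf`` for models that failed
    (singular even after jitter) in any fold of that repeat.
    """
    n, d = X.shape
    if n != plan.n:
        raise ValueError("design rows do not match the fold plan")
    M = len(col_sets)
    groups = _group_by_size(col_sets)
    rmse = np.zeros((plan.R, M))
    for r in range(plan.R):
        labels = plan.assignment[r]
        # per-fold sufficient statistics
        G_f = np.empty((plan.K, d, d))
        c_f = np.empty((plan.K, d))
        s_f = np.empty(plan.K)
        for k in range(plan.K):
            rows = labels == k
            Xk = X[rows]
            yk = y[rows]
            G_f[k] = Xk.T @ Xk
            c_f[k] = Xk.T @ yk
            s_f[k] = yk @ yk
        G_tot, c_tot, s_tot = G_f.sum(0), c_f.sum(0), s_f.sum()
        sse = np.zeros(M)
        for p, (members, idx) in groups.items():
            # gather total-Gram submatrices once per repeat
            Gt = G_tot[idx[:, :, None], idx[:, None, :]]
            ct = c_tot[idx]
            for k in range(plan.K):
                Gk = G_f[k][idx[:, :, None], idx[:, None, :]]
                ck = c_f[k][idx]
                if inverted_folds:
                    G_tr, c_tr = Gk, ck
                    G_te, c_te, s_te = Gt - Gk, ct - ck, s_tot - s_f[k]
                else:
                    G_tr, c_tr = Gt - Gk, ct - ck
                    G_te, c_te, s_te = Gk, ck, s_f[k]
                beta = _batched_solve(G_tr, c_tr)
                fold_sse = (s_te - 2.0 * np.einsum("mi,mi->m", beta, c_te)
                            + np.einsum("mi,mij,mj->m", beta, G_te, beta))
                np.add.at(sse, members, fold_sse)
        n_test = n * (plan.K - 1) if inverted_folds else n
        with np.errstate(invalid="ignore"):
            row = np.sqrt(np.maximum(sse, 0.0) / n_test)
        row[~np.isfinite(sse)] = np.inf
        rmse[r] = row
    return rmse


def _batched_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a stack of linear systems; singular members become NaN.

    The fast path is one batched LAPACK call; if any member is singular the
    stack is re-solved one by one through :func:`fit_linear_suffstats`'s
    jitter fallback.
    """
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        eye = np.eye(A.shape[-1])
        for m in range(A.shape[0]):
            try:
                out[m] = np.linalg.solve(A[m], b[m])
            except np.linalg.LinAlgError:
                try:
                    warnings.warn("singular training Gram submatrix; "
                                  "applying diagonal jitter", UserWarning)
                    out[m] = np.linalg.solve(A[m] + SINGULAR_JITTER * eye,
                                             b[m])
                except np.linalg.LinAlgError:
                    out[m] = np.nan
        return out


@dataclass
class CVRunResult:
    """Outcome of a step-1 selection run."""

    models: list[ModelSpec]
    rmse: np.ndarray                 # (R, M) per-repeat pooled RMSE_p
    win_counts: np.ndarray           # (M,) repeats won
    winner: ModelSpec
    plan: FoldPlan
    discarded_repeats: int = 0

    @property
    def win_percent(self) -> np.ndarray:
        return 100.0 * self.win_counts / self.win_counts.sum()

    @property
    def inclusion_frequency(self) -> pd.Series:
        """Fraction of winning repeats in which each effect is included."""
        effects = self.models[0].effects
        freq = np.zeros(effects.n_effects)
        total = self.win_counts.sum()
        for m, spec in enumerate(self.models):
            if self.win_counts[m]:
                for i in spec.included:
                    freq[i] += self.win_counts[m]
        return pd.Series(freq / total, index=list(effects.labels))


def _model_col_sets(models: list[ModelSpec]) -> list[np.ndarray]:
    return [np.concatenate(([0], np.asarray(spec.included) + 1))
            for spec in models]


def run_cv_selection(dataset: pd.DataFrame, effects: CandidateEffectSet,
                     K: int = 10, R: int = 200, seed: int = 0,
                     inverted_folds: bool = False,
                     max_models: int | None = None,
                     outcome: str = "harsh_discipline",
                     models: list[ModelSpec] | None = None) -> CVRunResult:
    """Step 1: repeated K-fold CV over every hierarchical candidate model.

    Rows are listwise-deleted over the union of all candidate variables
    before fold assignment, so every model sees identical rows and splits.
    Returns per-repeat RMSE_p for every model, win counts, and the run
    winner (most repeats won; ties to fewest parameters, then lowest mask).
    """
    if models is None:
        models = enumerate_models(effects)
    if max_models is not None:
        models = models[:max_models]
    X, y, _ = build_full_design(dataset, effects, outcome=outcome)
    plan = make_fold_plan(len(y), K, R, seed)
    col_sets = _model_col_sets(models)
    rmse = evaluate_masks(X, y, col_sets, plan,
                          inverted_folds=inverted_folds)
    # precedence order: fewest parameters, then lowest mask
    order = np.array(sorted(range(len(models)),
                            key=lambda m: (models[m].n_params,
                                           models[m].mask)))
    win_counts = np.zeros(len(models), dtype=int)
    discarded = 0
    for r in range(plan.R):
        row = rmse[r, order]
        if not np.isfinite(row).any():
            discarded += 1
            warnings.warn(f"repeat {r}: all models failed; repeat discarded",
                          UserWarning)
            continue
        win_counts[order[int(np.argmin(row))]] += 1
    if discarded > MAX_DISCARDED_FRACTION * plan.R:
        raise RuntimeError(f"{discarded}/{plan.R} repeats discarded; "
                           "selection aborted")
    winner = models[order[int(np.argmin(
        -win_counts[order]))]]  # most wins; order breaks ties
    return CVRunResult(models=models, rmse=rmse, win_counts=win_counts,
                       winner=winner, plan=plan,
                       discarded_repeats=discarded)


def wins_table(result: CVRunResult, top: int = 3) -> pd.DataFrame:
    """Top models by win count, with win % and mean RMSE_p."""
    finite = np.isfinite(result.rmse)
    mean_rmse = np.where(finite.all(axis=0), result.rmse.mean(axis=0), np.inf)
    rows = []
    order = np.argsort(-result.win_counts, kind="stable")[:top]
    for m in order:
        spec = result.models[m]
        rows.append({
            "mask": spec.mask,
            "effects": " + ".join(spec.labels),
            "n_params": spec.n_params,
            "wins": int(result.win_counts[m]),
            "win_percent": float(result.win_percent[m]),
            "mean_rmse": float(mean_rmse[m]),
        })
    return pd.DataFrame(rows)
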