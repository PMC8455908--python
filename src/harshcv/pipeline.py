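"""Full-pipeline orchestration: score, describe, select, fit, transfer.

``run_full_analysis`` executes both analysis steps for every configured
dataset and writes all tables as CSV plus a JSON manifest recording the
config hash, seeds, and package version.  Any stage failure aborts the run
with a stage-named error; outputs produced so far are retained next to a
``FAILED`` marker file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .cv_engine import run_cv_selection, wins_table
from .descriptives import summarize_countries
from .robust_fit import fit_winning_model
from .scales import score_dataset
from .transfer import cross_validate_models, plot_tables

log = logging.getLogger("harshcv")

__all__ = ["run_full_analysis", "PipelineError"]

CONTINUOUS_VARS = ("mother_age", "age_youngest", "marital_conflict",
                   "psychopathology", "health_concerns", "work_changes",
                   "work_stress", "father_involvement", "harsh_discipline")
CATEGORICAL_VARS = ("education", "income", "garden", "n_children",
                    "grandparent_care")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# harshcv {__version__} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_full_analysis(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    effects = config.effect_set()
    manifest: dict = {"version": __version__, "config_hash": cfg_hash,
                      "seed": config.seed, "outputs": []}
    stage = "validate"
    try:
        datasets: dict[str, pd.DataFrame] = {}
        for name, path in config.datasets.items():
            df = pd.read_csv(path, comment="#")
            needed = set(config.mains) | {config.outcome}
            mapped = set(config.manifests.get(name, {}))
            missing = sorted(needed - set(df.columns) - mapped)
            if missing:
                raise PipelineError(
                    f"[{stage}] dataset '{name}' lacks columns {missing}")
            datasets[name] = df

        stage = "score"
        for name, df in list(datasets.items()):
            man = config.manifests.get(name)
            if man:
                keep = [c for c in df.columns
                        if c in set(config.mains) | {config.outcome}]
                scored = score_dataset(df, man, passthrough=keep)
                datasets[name] = scored
            _write_csv(datasets[name], out / f"scored_{name}.csv", cfg_hash)
            manifest["outputs"].append(f"scored_{name}.csv")

        stage = "describe"
        cont = [v for v in CONTINUOUS_VARS
                if all(v in d.columns for d in datasets.values())]
        cat = [v for v in CATEGORICAL_VARS
               if all(v in d.columns for d in datasets.values())]
        desc = summarize_countries(datasets, continuous=cont,
                                   categorical=cat)
        _write_csv(desc, out / "descriptives.csv", cfg_hash)
        manifest["outputs"].append("descriptives.csv")

        stage = "select"
        seeds = np.random.SeedSequence(config.seed).spawn(len(datasets) + 1)
        winners = {}
        for (name, df), child in zip(datasets.items(), seeds):
            log.info("selecting model for %s", name)
            sel = run_cv_selection(
                df, effects, K=config.K, R=config.repeats,
                seed=int(child.generate_state(1)[0] % (2 ** 31)),
                inverted_folds=config.inverted_folds,
                max_models=config.max_models, outcome=config.outcome)
            winners[name] = sel.winner
            _write_csv(wins_table(sel, top=10), out / f"wins_{name}.csv",
                       cfg_hash)
            manifest["outputs"].append(f"wins_{name}.csv")

        stage = "fit"
        for name, df in datasets.items():
            fit = fit_winning_model(df, winners[name],
                                    outcome=config.outcome, c=config.huber_c)
            tbl = fit.table().reset_index(names="effect")
            tbl.loc[len(tbl)] = {"effect": "adjusted_R2",
                                 "beta": fit.adj_r2, "se": np.nan,
                                 "z": np.nan, "p": np.nan}
            _write_csv(tbl, out / f"coefficients_{name}.csv", cfg_hash)
            manifest["outputs"].append(f"coefficients_{name}.csv")

        stage = "transfer"
        res = cross_validate_models(
            datasets, winners, K=config.K, R=config.repeats,
            seed=int(seeds[-1].generate_state(1)[0] % (2 ** 31)),
            outcome=config.outcome, inverted_folds=config.inverted_folds)
        quant, dens = plot_tables(res)
        _write_csv(quant, out / "transfer_quantiles.csv", cfg_hash)
        _write_csv(dens, out / "transfer_density.csv", cfg_hash)
        win_rows = [{"dataset": ds, "model": cand, "win_percent": w}
                    for ds, d in res.win_percent.items()
                    for cand, w in d.items()]
        _write_csv(pd.DataFrame(win_rows), out / "transfer_wins.csv",
                   cfg_hash)
        manifest["outputs"] += ["transfer_quantiles.csv",
                                "transfer_density.csv", "transfer_wins.csv"]
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"[{stage}] {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
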