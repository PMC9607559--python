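"""End-to-end runs: split -> select -> sweep -> fit -> evaluate, with manifests.

A run is described by a YAML config (per-stage sections, all defaults
pre-populated) and produces a run directory containing stage artifacts plus a
``manifest.json`` recording the config snapshot, seeds, package version and
SHA-256 digests of the inputs — enough to re-execute deterministic stages
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    DescriptorTable,
    apply_minmax,
    fit_minmax,
    kennard_stone_split,
    load_table,
    remove_constant_columns,
    save_split,
)
from .ga import GAConfig, choose_subset_size, rank_descriptors, run_ga, sweep_subset_sizes
from .modeling import ModelSpec, evaluate
from .screening import ScreenConfig, grid_search, pearson_prefilter
from .synthetic import SyntheticSpec, make_planted

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "split": {"n_train": None},  # None -> ~80% of rows
    "select": {
        "method": "ga",          # ga | grid
        "variant": "rec",        # o | re | rec
        "model": "pls",
        "population": 50,
        "generations": 200,
        "pc": 0.5,
        "pm": 0.01,
        "cv_folds": 5,
        "history_window": 50,
        "n_keep": 30,
        # grid-search settings
        "relevance_min": 0.1,
        "redundancy_max": 0.5,
        "n_repeats": 10,
        "early_stop_tol": 0.01,
    },
    "model": {"family": "svr", "pca_components": 5, "params": {}},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_CONFIG, user)


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stage chain; returns the run directory.

    The documented default profile is the GA with elitism and history-adaptive
    mutation (variant ``rec``), followed by a PCA + SVR model.  A stage
    failure halts the run with the stage name; the partial manifest is
    persisted.
    """
    config = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
        "stages": {},
    }

    def persist() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        stage = "load"
        if "synthetic" in config:
            sy = config["synthetic"]
            spec = SyntheticSpec(
                n_samples=sy.get("n_samples", 30),
                n_descriptors=sy.get("n_descriptors", 200),
                n_informative=sy.get("n_informative", 5),
                noise_sigma=sy.get("noise_sigma", 0.5),
                n_constant=sy.get("n_constant", 5),
                n_duplicates=sy.get("n_duplicates", 5),
                rng_seed=sy.get("rng_seed", seed),
            )
            table, truth = make_planted(spec)
            (out / "ground_truth.json").write_text(
                json.dumps({"informative": truth.informative_names}, indent=2)
            )
            manifest["stages"]["load"] = {"source": "synthetic", "spec": asdict(spec)}
        else:
            matrix = config["input"]["matrix"]
            target = config["input"].get("target")
            table = load_table(matrix, target)
            manifest["inputs"] = {
                "matrix": {"path": str(matrix), "sha256": _sha256(matrix)},
            }
            if target:
                manifest["inputs"]["target"] = {"path": str(target), "sha256": _sha256(target)}
            manifest["stages"]["load"] = {"n_samples": table.n_samples,
                                          "n_descriptors": table.n_descriptors}
        persist()

        stage = "clean"
        table, removed = remove_constant_columns(table)
        manifest["stages"]["clean"] = {"removed_constant": removed}
        persist()

        stage = "split"
        n_train = config["split"]["n_train"] or max(2, round(0.8 * table.n_samples))
        split = kennard_stone_split(table, int(n_train))
        save_split(split, table, out / "split.csv")
        manifest["stages"]["split"] = {
            "n_train": len(split.train_indices),
            "n_test": len(split.test_indices),
            "artifact": "split.csv",
        }
        persist()

        scaler = fit_minmax(table, split.train_indices)
        scaled = apply_minmax(scaler, table)
        train = scaled.subset_rows(split.train_indices)
        test = scaled.subset_rows(split.test_indices) if split.test_indices else None

        stage = "select"
        sel = config["select"]
        if sel["method"] == "ga":
            ga_cfg = GAConfig(
                population_size=int(sel["population"]),
                generations=int(sel["generations"]),
                crossover_prob=float(sel["pc"]),
                mutation_prob=float(sel["pm"]),
                cv_folds=int(sel["cv_folds"]),
                variant=sel["variant"],
                history_window=int(sel["history_window"]),
                rng_seed=seed,
            )
            fit_model = ModelSpec(family=sel["model"], rng_seed=seed)
            report = run_ga(train, fit_model, ga_cfg)
            pd.DataFrame({"generation": range(len(report.best_fitness_trace)),
                          "best_fitness": report.best_fitness_trace}).to_csv(
                out / "trace.csv", index=False)
            freq = report.descriptor_frequencies()
            pd.DataFrame({"descriptor": report.descriptor_names,
                          "frequency": freq}).sort_values(
                "frequency", ascending=False).to_csv(out / "frequencies.csv", index=False)
            n_keep = min(int(sel["n_keep"]), train.n_descriptors)
            ranked = rank_descriptors(report, n_keep, values=train.values)

            stage = "sweep"
            sizes = list(range(1, len(ranked) + 1))
            curve = sweep_subset_sizes(ranked, train, fit_model, sizes, test=test,
                                       folds=int(sel["cv_folds"]), rng_seed=seed)
            pd.DataFrame(curve).to_csv(out / "sweep.csv", index=False)
            chosen = ranked[: choose_subset_size(curve)]
        else:
            screen_cfg = ScreenConfig(
                relevance_min=float(sel["relevance_min"]),
                redundancy_max=float(sel["redundancy_max"]),
                cv_folds=int(sel["cv_folds"]),
                n_repeats=int(sel["n_repeats"]),
                early_stop_tol=float(sel["early_stop_tol"]),
                rng_seed=seed,
            )
            filtered = pearson_prefilter(train, screen_cfg)
            result = grid_search(train, filtered, sel["model"], screen_cfg)
            pd.DataFrame(result.table).to_csv(out / "grid.csv", index=False)
            chosen = result.subset_names
            manifest["stages"]["grid"] = {"params": result.params,
                                          "cv_score": result.cv_score}
        (out / "chosen_subset.txt").write_text("\n".join(chosen) + "\n")
        manifest["stages"]["select"] = {"method": sel["method"], "chosen": chosen}
        persist()

        stage = "evaluate"
        mc = config["model"]
        pca = mc.get("pca_components")
        if pca is not None:
            pca = min(int(pca), len(chosen), len(split.train_indices))
        spec = ModelSpec(family=mc["family"], pca_components=pca,
                         params=dict(mc.get("params") or {}), rng_seed=seed)
        final = scaled.subset_columns(chosen)
        ev = evaluate(spec, split, final, folds=int(sel["cv_folds"]), rng_seed=seed)
        (out / "eval.json").write_text(json.dumps(ev.to_dict(), indent=2))
        manifest["stages"]["evaluate"] = ev.to_dict()
        persist()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        raise StageError(stage, exc) from exc

    return out


def verify_manifest(run_dir: str | Path) -> bool:
    """Re-read the run's inputs and check their digests still match."""
    manifest = json.loads((Path(run_dir) / "manifest.json").read_text())
    for entry in manifest.get("inputs", {}).values():
        if _sha256(entry["path"]) != entry["sha256"]:
            return False
    return True
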