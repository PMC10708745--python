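"""End-to-end experiment runner: config in, report bundle on disk out.

A run executes, per variety: wavelength decimation, the single-output sweep
(algorithms x spectral sources), optional multi-output models, and finally
the attention CNN -- all on the same stratified fold plan -- then writes a
tidy metrics CSV, a Markdown summary of best models, and the CNN wavelength
importance profiles.  Every stage logs its seed and chosen hyperparameters,
and a run is fully reproducible from its config plus seed (single-threaded).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import baselines, evaluation, interpret, io, mimo, pretreat, simulate

logger = logging.getLogger(__name__)

DEFAULT_FACTOR = 10


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("experiment config must be a mapping")
    return cfg


def _get_library(cfg: Mapping[str, Any]) -> io.SpectralLibrary:
    if "input" in cfg:
        return io.read_library(cfg["input"])
    if "simulate" in cfg:
        return simulate.generate_library(**(cfg["simulate"] or {}))
    raise ValueError("config needs either an 'input' path or a 'simulate' block")


def _single_specs(fam_cfg: Mapping[str, Any], targets) -> list[evaluation.ModelSpec]:
    algorithms = fam_cfg.get("algorithms", list(baselines.ALGORITHMS))
    sources = fam_cfg.get("sources", list(pretreat.SOURCES))
    return [
        evaluation.ModelSpec("single", algorithm=a.upper(),
                             source=s.upper().replace("+", "_"), target=t)
        for t in targets
        for a in algorithms
        for s in sources
    ]


def _multi_specs(fam_cfg: Mapping[str, Any]) -> list[evaluation.ModelSpec]:
    algorithms = fam_cfg.get("algorithms", ["PLS", "RF"])
    sources = fam_cfg.get("sources", list(pretreat.SOURCES))
    return [
        evaluation.ModelSpec("multi", algorithm=a.upper(),
                             source=s.upper().replace("+", "_"))
        for a in algorithms
        for s in sources
    ]


def run_experiment(config: Mapping[str, Any] | str | Path,
                   out_dir: str | Path | None = None,
                   seed: Optional[int] = None) -> Path:
    """Run a configured experiment; returns the results directory."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir or config.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    k = int(config.get("k", 5))
    targets = list(config.get("targets", evaluation.TARGETS))
    factor = int(config.get("subsample_factor", DEFAULT_FACTOR))
    families = config.get("families", {"single": {}})

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    root = logging.getLogger("vitispec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        lib = _get_library(config)
        logger.info("library: n=%d L=%d seed=%d", len(lib), len(lib.grid), seed)
        lib = io.subsample_wavelengths(lib, factor)
        logger.info("decimation factor %d -> L=%d", factor, len(lib.grid))

        metric_rows = []
        for variety in sorted(set(lib.varieties().tolist())):
            vlib = lib.subset(np.flatnonzero(lib.varieties() == variety))
            plan = evaluation.make_stratified_folds(vlib.dates(), k=k, seed=seed)
            logger.info("variety=%s n=%d folds=%d seed=%d",
                        variety, len(vlib), plan.k, seed)
            reports = []

            if "single" in families:
                for spec in _single_specs(families["single"] or {}, targets):
                    rep = evaluation.nested_cv(vlib, spec, seed=seed, plan=plan)
                    reports.append(rep)
                    _log_report(variety, rep)
            if "multi" in families:
                for spec in _multi_specs(families["multi"] or {}):
                    rep = evaluation.nested_cv(vlib, spec, seed=seed, plan=plan)
                    reports.append(rep)
                    _log_report(variety, rep)
            if "cnn" in families:
                cnn_cfg = dict(families["cnn"] or {})
                train_cfg = mimo.TrainingConfig(
                    epochs=int(cnn_cfg.get("epochs", 100)),
                    batch_size=int(cnn_cfg.get("batch_size", 16)),
                    patience=int(cnn_cfg.get("patience", 50)),
                    seed=seed,
                )
                rep = evaluation.nested_cv(
                    vlib, evaluation.ModelSpec("cnn"), seed=seed, plan=plan,
                    cnn_config=train_cfg, collect_attention=True,
                )
                reports.append(rep)
                _log_report(variety, rep)
                profile = interpret.aggregate_folds(
                    rep.importance_profiles, vlib.grid, variety=variety
                )
                _write_importance(out, variety, profile)

            for rep in reports:
                df = rep.fold_metrics.copy()
                df.insert(0, "variety", variety)
                df.insert(1, "family", rep.spec.family)
                df.insert(2, "algorithm", rep.spec.label)
                df.insert(
                    3, "source",
                    rep.spec.source or "+".join(mimo.CHANNEL_SOURCES),
                )
                metric_rows.append(df)

        metrics = pd.concat(metric_rows, ignore_index=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        make_report(out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


def _log_report(variety: str, rep: evaluation.NestedCVReport) -> None:
    for fold, params in enumerate(rep.chosen_params):
        logger.info("variety=%s family=%s model=%s source=%s fold=%d chosen=%s",
                    variety, rep.spec.family, rep.spec.label,
                    rep.spec.source, fold, json.dumps(params))


def _write_importance(out: Path, variety: str,
                      profile: interpret.ImportanceProfile) -> None:
    pd.DataFrame(
        {"wavelength_nm": profile.grid.values,
         "importance": profile.importance}
    ).to_csv(out / f"importance_{variety}.csv", index=False)
    top = interpret.top_k(profile, k=min(5, len(profile.grid)))
    with open(out / f"top_wavelengths_{variety}.json", "w") as fh:
        json.dump(
            [{"wavelength_nm": w, "importance": v} for w, v in top], fh,
            indent=2,
        )


def _mean_table(metrics: pd.DataFrame) -> pd.DataFrame:
    return (
        metrics.groupby(
            ["variety", "family", "algorithm", "source", "target"], sort=False
        )[["rmse", "r2", "rpiq"]]
        .mean()
        .reset_index()
    )


def make_report(results_dir: str | Path) -> Path:
    """Summarize a results directory into Markdown + a barplot-ready CSV.

    Best single-output rows use the same ordering as
    :func:`vitispec.evaluation.select_best`: highest mean R2, ties by lower
    RMSE then lexicographic source.
    """
    results_dir = Path(results_dir)
    metrics_path = results_dir / "metrics.csv"
    if not metrics_path.exists():
        raise FileNotFoundError(f"no metrics.csv under {results_dir}")
    means = _mean_table(pd.read_csv(metrics_path))
    means.to_csv(results_dir / "mean_metrics.csv", index=False)

    lines = ["# Experiment summary", ""]
    single = means[means["family"] == "single"]
    if not single.empty:
        lines += ["## Best single-output model per variety and target", ""]
        best = (
            single.sort_values(
                by=["variety", "target", "r2", "rmse", "source"],
                ascending=[True, True, False, True, True], kind="mergesort",
            )
            .groupby(["variety", "target"], sort=False)
            .head(1)
        )
        lines += _md_table(best)
    multi = means[means["family"].isin(["multi", "cnn"])]
    if not multi.empty:
        lines += ["", "## Multi-output models", ""]
        lines += _md_table(multi)
    report = results_dir / "summary.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _md_table(df: pd.DataFrame) -> list[str]:
    cols = ["variety", "target", "family", "algorithm", "source",
            "rmse", "r2", "rpiq"]
    df = df[cols]
    header = "| " + " | ".join(cols) + " |"
    sep = "|" + "---|" * len(cols)
    rows = [
        "| " + " | ".join(
            f"{v:.3f}" if isinstance(v, float) else str(v) for v in rec
        ) + " |"
        for rec in df.itertuples(index=False)
    ]
    return [header, sep, *rows]
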