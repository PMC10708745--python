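"""Accuracy metrics and the nested stratified cross-validation engine.

Metrics
-------
RMSE, the coefficient of determination R2 = 1 - SS_res/SS_tot, and RPIQ =
(Q3 - Q1)/RMSE, the interquartile range of the observations over the
prediction error.  Quartiles use the linear-interpolation convention
(NumPy's default), which RPIQ values depend on.

Cross-validation
----------------
The outer loop is a stratified 5-fold split with the sampling dates as
strata, so each fold covers the whole maturation trajectory; every model
family is evaluated on the same :class:`FoldPlan`.  Within each outer fold,
hyperparameters are selected by an inner 5-fold grid search on the
calibration rows only (:func:`vitispec.baselines.inner_grid_search`), after
which the model is refitted on the full calibration set and scored on the
held-out fold.  Mean scores are the arithmetic mean of per-fold metrics,
not pooled predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import baselines, mimo, pretreat
from .io import SpectralLibrary

TARGETS = ("brix", "ph", "ta")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination about the observed mean.

    Exactly 1 for a perfect predictor and exactly 0 for the constant
    mean predictor; negative values indicate performance below that
    baseline.
    """
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined for constant observations")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def rpiq(y: np.ndarray, yhat: np.ndarray) -> float:
    """Interquartile range of y over RMSE (distribution-free skill ratio)."""
    y, yhat = _check_pair(y, yhat)
    q1, q3 = np.percentile(y, [25, 75])  # linear interpolation convention
    err = rmse(y, yhat)
    if err == 0:
        warnings.warn("RMSE is zero; RPIQ is infinite", RuntimeWarning)
        return float("inf")
    return float((q3 - q1) / err)


def metrics_triplet(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    return {"rmse": rmse(y, yhat), "r2": r2(y, yhat), "rpiq": rpiq(y, yhat)}


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """A k-way partition of sample indices, stratified by date labels."""

    folds: list[np.ndarray]
    strata: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def splits(self):
        """(calibration_indices, test_indices) per outer fold."""
        all_idx = np.arange(self.strata.size)
        for fold in self.folds:
            mask = np.ones(self.strata.size, dtype=bool)
            mask[fold] = False
            yield all_idx[mask], fold


def make_stratified_folds(
    dates: Sequence, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Deterministic stratified k-fold plan with dates as strata.

    Each stratum's samples are shuffled and dealt round-robin, with the
    starting fold rotating by the number already dealt so fold sizes stay
    balanced; per-stratum fold counts differ by at most one.
    """
    dates = np.asarray(dates)
    n = dates.size
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for stratum in sorted(set(dates.tolist())):
        idx = np.flatnonzero(dates == stratum)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset += idx.size
    return FoldPlan([np.array(sorted(f), dtype=int) for f in folds], dates, seed)


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to evaluate: a model family x spectral source (x target).

    family 'single': one algorithm (PLS/RF/SVR), one source, one target.
    family 'multi':  PLS or RF predicting all three targets jointly.
    family 'cnn':    the multi-input attention CNN (source/algorithm fixed).
    """

    family: str
    algorithm: Optional[str] = None
    source: Optional[str] = None
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in ("single", "multi", "cnn"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "single":
            if self.target not in TARGETS:
                raise ValueError("single-output spec needs a target")
            if self.algorithm is None or self.source is None:
                raise ValueError("single-output spec needs algorithm and source")
        if self.family == "multi":
            if self.algorithm not in ("PLS", "RF"):
                raise ValueError("multi-output models exist for PLS and RF only")
            if self.source is None:
                raise ValueError("multi-output spec needs a source")

    @property
    def label(self) -> str:
        if self.family == "cnn":
            return "CNN"
        return f"{self.algorithm}"


@dataclass
class NestedCVReport:
    """Per-fold metrics plus per-fold chosen hyperparameters."""

    spec: ModelSpec
    fold_metrics: pd.DataFrame  # columns: target, fold, rmse, r2, rpiq
    chosen_params: list[dict[str, Any]]
    importance_profiles: Optional[list[np.ndarray]] = None
    histories: Optional[list[pd.DataFrame]] = None

    def mean_metrics(self) -> pd.DataFrame:
        """Arithmetic mean of per-fold metrics, per target."""
        return (
            self.fold_metrics.groupby("target", sort=False)[
                ["rmse", "r2", "rpiq"]
            ]
            .mean()
            .reset_index()
        )


def _fold_seed(seed: int, fold: int) -> int:
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(fold,)).generate_state(1)[0]
        % (2**31)
    )


def nested_cv(
    lib: SpectralLibrary,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    plan: FoldPlan | None = None,
    cnn_config: "mimo.TrainingConfig | None" = None,
    collect_attention: bool = False,
) -> NestedCVReport:
    """Nested stratified CV for one model specification.

    All transforms with cross-sample state (CNN channel scaling, target
    standardization) are fitted on calibration rows inside each fold; the
    spectral pre-treatments themselves are per-spectrum and fold-safe.
    Passing the same ``plan`` to successive calls evaluates every model
    family on identical folds.
    """
    if not lib.has_targets:
        raise ValueError("library records lack maturity targets")
    if plan is None:
        plan = make_stratified_folds(lib.dates(), k=k, seed=seed)

    if spec.family == "cnn":
        return _nested_cv_cnn(lib, spec, plan, seed, cnn_config, collect_attention)

    targets = [spec.target] if spec.family == "single" else list(TARGETS)
    X = pretreat.apply_source(lib, spec.source)
    Y = lib.target_matrix(targets)

    rows = []
    chosen = []
    for fold_id, (cal, test) in enumerate(plan.splits()):
        fseed = _fold_seed(seed, fold_id)
        search = baselines.inner_grid_search(
            spec.algorithm, X[cal], Y[cal], k=plan.k, seed=fseed
        )
        params = search.selected_params
        model = baselines.fit(spec.algorithm, X[cal], Y[cal], params, seed=fseed)
        pred = baselines.predict(model, X[test])
        chosen.append(dict(params))
        for j, t in enumerate(targets):
            rows.append(
                {"target": t, "fold": fold_id,
                 **metrics_triplet(Y[test][:, j], pred[:, j])}
            )
    return NestedCVReport(spec, pd.DataFrame(rows), chosen)


def _nested_cv_cnn(lib, spec, plan, seed, cnn_config, collect_attention):
    from . import interpret  # local import; interpret has no cv dependency

    cfg = cnn_config or mimo.TrainingConfig()
    X3 = mimo.stack_channels(lib)
    Y = lib.target_matrix(TARGETS)
    L = X3.shape[1]

    rows, chosen, profiles, histories = [], [], [], []
    for fold_id, (cal, test) in enumerate(plan.splits()):
        fseed = _fold_seed(seed, fold_id)
        scaler = mimo.ChannelScaler().fit(X3[cal])
        Xcal, Xtest = scaler.transform(X3[cal]), scaler.transform(X3[test])
        model = mimo.build_network(L, D=X3.shape[2], seed=fseed)
        fold_cfg = mimo.TrainingConfig(
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, patience=cfg.patience,
            val_fraction=cfg.val_fraction, seed=fseed,
        )
        hist = mimo.train(model, Xcal, Y[cal], fold_cfg)
        histories.append(hist)
        pred = model.predict(Xtest)
        chosen.append({"epochs_run": int(hist["epoch"].iloc[-1]) + 1})
        for j, t in enumerate(TARGETS):
            rows.append(
                {"target": t, "fold": fold_id,
                 **metrics_triplet(Y[test][:, j], pred[:, j])}
            )
        if collect_attention:
            att = model.attention_weights(Xtest)
            profiles.append(interpret.weighted_importance(att, Xtest))
    return NestedCVReport(
        spec, pd.DataFrame(rows), chosen,
        importance_profiles=profiles if collect_attention else None,
        histories=histories,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def summarize_reports(reports: Sequence[NestedCVReport]) -> pd.DataFrame:
    """Tidy per-(model, target) mean metrics across folds."""
    rows = []
    for rep in reports:
        for _, r in rep.mean_metrics().iterrows():
            rows.append(
                {"family": rep.spec.family, "algorithm": rep.spec.label,
                 "source": rep.spec.source or "+".join(mimo.CHANNEL_SOURCES),
                 "target": r["target"], "rmse": r["rmse"], "r2": r["r2"],
                 "rpiq": r["rpiq"]}
            )
    return pd.DataFrame(rows)


def select_best(
    reports: Sequence[NestedCVReport], mode: str = "single"
) -> pd.DataFrame:
    """Best configuration(s) by highest mean R2.

    mode 'single': best (algorithm x source) independently per target.
    mode 'multi':  best (algorithm x source) by mean R2 across the three
    targets.  Ties break by lower mean RMSE, then lexicographic source.
    """
    if not reports:
        raise ValueError("empty report set")
    summary = summarize_reports(reports)
    if mode == "single":
        frames = []
        for t, group in summary.groupby("target", sort=False):
            ordered = group.sort_values(
                by=["r2", "rmse", "source"], ascending=[False, True, True],
                kind="mergesort",
            )
            frames.append(ordered.iloc[[0]])
        return pd.concat(frames, ignore_index=True)
    if mode == "multi":
        agg = (
            summary.groupby(["family", "algorithm", "source"], sort=False)
            .agg(r2=("r2", "mean"), rmse=("rmse", "mean"))
            .reset_index()
            .sort_values(by=["r2", "rmse", "source"],
                         ascending=[False, True, True], kind="mergesort")
        )
        best = agg.iloc[0]
        return summary[
            (summary["algorithm"] == best["algorithm"])
            & (summary["source"] == best["source"])
        ].reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")
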