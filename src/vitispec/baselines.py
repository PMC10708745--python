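"""PLS, random-forest and SVR learners with their hyperparameter grids.

Single-output models exist for all three algorithms; multi-output (three
correlated targets at once) only for PLS and RF, since epsilon-SVR is
inherently single-response.  Hyperparameters are chosen by grid search with
k-fold CV on calibration data only (the inner loop of the nested CV driven
by :mod:`vitispec.evaluation`):

* PLS -- number of latent variables in [1, 100];
* RF  -- trees in {50, 100, 150, 200} x feature rule {max, sqrt, log2},
  where "max" means all features are candidates at every split;
* SVR (RBF kernel) -- epsilon in {0.01, 0.025, 0.05, 0.075, 0.10, 0.15,
  0.20} x cost C in {2^-2, ..., 2^9}.

The inner selection metric is the RMSE averaged over left-out folds; for
multi-output fits each target's RMSE is first divided by the calibration
standard deviation of that target so that degrees Brix, pH units and g/L
acidity contribute on a common scale.  Candidate lists are ordered from
simplest to most complex, and ties keep the earliest (simplest) candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

ALGORITHMS = ("PLS", "RF", "SVR")

PLS_MAX_COMPONENTS = 100
RF_TREES = (50, 100, 150, 200)
RF_FEATURE_RULES = ("max", "sqrt", "log2")
SVR_EPSILONS = (0.01, 0.025, 0.05, 0.075, 0.10, 0.15, 0.20)
SVR_COSTS = tuple(2.0**k for k in range(-2, 10))


class ArityError(ValueError):
    """Multi-output requested from a single-response learner."""


@dataclass(frozen=True)
class HyperGrid:
    algorithm: str
    candidates: tuple[dict[str, Any], ...]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.candidates:
            raise ValueError("empty hyperparameter grid")

    def __len__(self) -> int:
        return len(self.candidates)


def default_grid(algorithm: str) -> HyperGrid:
    """The grid searched for each algorithm (sizes 100 / 12 / 84).

    Candidates are listed simplest-first: ascending latent variables for
    PLS; ascending trees (then the feature-rule order max, sqrt, log2) for
    RF; ascending cost then descending epsilon for SVR.
    """
    algorithm = algorithm.upper()
    if algorithm == "PLS":
        cands = tuple(
            {"n_components": k} for k in range(1, PLS_MAX_COMPONENTS + 1)
        )
    elif algorithm == "RF":
        cands = tuple(
            {"n_estimators": t, "max_features": f}
            for t in RF_TREES
            for f in RF_FEATURE_RULES
        )
    elif algorithm == "SVR":
        cands = tuple(
            {"C": c, "epsilon": e}
            for c in SVR_COSTS
            for e in sorted(SVR_EPSILONS, reverse=True)
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return HyperGrid(algorithm, cands)


@dataclass
class FittedModel:
    algorithm: str
    params: dict[str, Any]
    estimator: Any
    n_outputs: int
    n_features: int
    seed: int


@dataclass
class InnerCVResult:
    grid: HyperGrid
    mean_errors: np.ndarray  # per-candidate mean validation RMSE (nan = infeasible)
    selected_index: int

    @property
    def selected_params(self) -> dict[str, Any]:
        return self.grid.candidates[self.selected_index]


def _make_estimator(algorithm: str, params: dict[str, Any], seed: int):
    if algorithm == "PLS":
        return PLSRegression(n_components=params["n_components"])
    if algorithm == "RF":
        mf = params["max_features"]
        return RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_features=1.0 if mf == "max" else mf,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVR":
        return SVR(kernel="rbf", C=params["C"], epsilon=params["epsilon"])
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit(
    algorithm: str,
    X: np.ndarray,
    Y: np.ndarray,
    params: dict[str, Any],
    seed: int = 0,
) -> FittedModel:
    """Train one model with fixed hyperparameters."""
    algorithm = algorithm.upper()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("missing or non-finite values in X or Y")
    n_outputs = Y.shape[1]
    if algorithm == "SVR" and n_outputs > 1:
        raise ArityError("SVR cannot fit multi-output targets")
    est = _make_estimator(algorithm, params, seed)
    with warnings.catch_warnings():
        # small folds can exhaust the Y residual before the requested number
        # of PLS components; the fit is still well-defined
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        est.fit(X, Y if n_outputs > 1 or algorithm == "PLS" else Y.ravel())
    return FittedModel(algorithm, dict(params), est, n_outputs, X.shape[1], seed)


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predictions with one column per trained output."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape}"
        )
    pred = model.estimator.predict(X)
    if pred.ndim == 1:
        pred = pred[:, None]
    return pred


def _rmse_matrix(Y: np.ndarray, pred: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((Y - pred) ** 2, axis=0))


def _pls_path_errors(
    X: np.ndarray,
    Y: np.ndarray,
    k_values: Sequence[int],
    splits,
    y_scale: np.ndarray,
) -> np.ndarray:
    """Mean validation RMSE for every latent-variable count in one pass.

    For each inner fold a single PLS decomposition is computed at the
    largest feasible component count; the coefficient matrix for k
    components is the truncation B_k = R[:, :k] Q[:, :k]^T of that
    decomposition (R = x_rotations, Q = y_loadings in the centred/scaled
    space), so the whole [1, 100] path costs one fit per fold.  Equivalence
    with per-k fits is covered by the test suite.
    """
    kmax_grid = max(k_values)
    errors = np.full((len(splits), len(k_values)), np.nan)
    for si, (tr, va) in enumerate(splits):
        Xtr, Ytr = X[tr], Y[tr]
        x_mean, y_mean = Xtr.mean(axis=0), Ytr.mean(axis=0)
        x_std = Xtr.std(axis=0, ddof=1)
        y_std = Ytr.std(axis=0, ddof=1)
        x_std[x_std == 0] = 1.0
        y_std[y_std == 0] = 1.0
        Xc = (Xtr - x_mean) / x_std
        Yc = (Ytr - y_mean) / y_std
        kmax = min(kmax_grid, len(tr) - 1, X.shape[1])
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*residual is constant.*")
            pls = PLSRegression(n_components=kmax, scale=False).fit(Xc, Yc)
        R, Q = pls.x_rotations_, pls.y_loadings_
        Xva = (X[va] - x_mean) / x_std
        T = Xva @ R  # validation scores, one column per component
        # cumulative sum over components of t_k q_k^T gives all truncations
        contrib = T[:, :, None] * Q.T[None, :, :]  # (n_va, kmax, q)
        cum = np.cumsum(contrib, axis=1)
        for ki, k in enumerate(k_values):
            if k > kmax:
                continue
            pred = cum[:, k - 1, :] * y_std + y_mean
            errors[si, ki] = np.mean(_rmse_matrix(Y[va], pred) / y_scale)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        return np.nanmean(errors, axis=0)


def inner_grid_search(
    algorithm: str,
    X: np.ndarray,
    Y: np.ndarray,
    grid: HyperGrid | None = None,
    k: int = 5,
    seed: int = 0,
) -> InnerCVResult:
    """k-fold grid search on calibration data; argmin of mean RMSE.

    Receives only calibration rows by construction, so test data can never
    influence hyperparameter choice.  Inner folds are plain shuffled K-fold
    seeded per call.  Infeasible candidates (PLS components exceeding the
    fold's sample budget) are excluded.
    """
    algorithm = algorithm.upper()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {X.shape[0]}")
    if grid is None:
        grid = default_grid(algorithm)
    if grid.algorithm != algorithm:
        raise ValueError("grid/algorithm mismatch")

    # common scale for multi-output selection; constant 1 for single output
    if Y.shape[1] > 1:
        y_scale = Y.std(axis=0, ddof=1)
        y_scale[y_scale == 0] = 1.0
    else:
        y_scale = np.ones(1)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    if algorithm == "PLS":
        k_values = [c["n_components"] for c in grid.candidates]
        mean_err = _pls_path_errors(X, Y, k_values, splits, y_scale)
    else:
        mean_err = np.full(len(grid), np.nan)
        for ci, cand in enumerate(grid.candidates):
            fold_err = []
            for tr, va in splits:
                m = fit(algorithm, X[tr], Y[tr], cand, seed=seed)
                pred = predict(m, X[va])
                fold_err.append(np.mean(_rmse_matrix(Y[va], pred) / y_scale))
            mean_err[ci] = np.mean(fold_err)

    if np.all(np.isnan(mean_err)):
        raise ValueError("no feasible candidate in the grid")
    best = int(np.nanargmin(mean_err))  # first minimum = simplest candidate
    return InnerCVResult(grid, mean_err, best)
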