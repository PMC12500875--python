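"""Predictive models on reduced feature sets.

Three model pathways are provided:

* :func:`fit_monomial` — the interpretable power-law model.  The
  dependent dimensionless group is modelled as a constant times the
  product of the independent pi-groups raised to fitted exponents,
  estimated by ordinary least squares in log space.
* :func:`train_ffnn` — a two-hidden-layer feedforward network (ReLU
  hidden units, linear output, Adam, L2 weight penalty) trained under a
  5-fold cross-validation protocol repeated over several seeds, with
  per-epoch train/validation MSE and MAE traces recorded for loss plots.
* :func:`train_ensemble` — ridge (CV-selected alpha, no intercept on
  standardized features), gradient boosting, random forest and RBF
  support-vector regressors with fixed, reproducible hyperparameters.

:func:`back_transform` converts predicted dimensionless ratios back to
dimensional effluent concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = [
    "MonomialModel",
    "fit_monomial",
    "predict_monomial",
    "FFNNConfig",
    "FFNNResult",
    "train_ffnn",
    "EnsembleConfig",
    "train_ensemble",
    "back_transform",
]


# ---------------------------------------------------------------------------
# monomial (power-law) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonomialModel:
    """log(pi_dep) = beta0 + sum_i beta_i * log(pi_i)."""

    beta0: float
    exponents: Mapping[str, float]

    @property
    def feature_names(self) -> list[str]:
        return list(self.exponents)


def _positive_log(features: pd.DataFrame, what: str) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{what} must be strictly positive and finite")
    return np.log(x)


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    full = np.linalg.matrix_rank(design)
    involved = []
    for j, name in enumerate(names):
        reduced = np.delete(design, j + 1, axis=1)  # +1 skips intercept
        if np.linalg.matrix_rank(reduced) == full:
            involved.append(name)
    return involved


def fit_monomial(pi_features: pd.DataFrame, dependent_pi) -> MonomialModel:
    """Ordinary least squares of log(dependent pi) on log(independent pi).

    Raises on non-positive values or a rank-deficient log design, naming
    the collinear columns.
    """
    if not isinstance(pi_features, pd.DataFrame):
        pi_features = pd.DataFrame(np.asarray(pi_features, dtype=float))
    names = [str(c) for c in pi_features.columns]
    logx = _positive_log(pi_features, "pi features")
    y = np.asarray(dependent_pi, dtype=float).ravel()
    if y.shape[0] != logx.shape[0]:
        raise ValueError("feature/target length mismatch")
    logy = np.log(y) if np.all(y > 0) else None
    if logy is None:
        raise ValueError("dependent pi must be strictly positive")
    design = np.column_stack([np.ones(len(logx)), logx])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient log design; collinear column(s): {bad}")
    coef, *_ = np.linalg.lstsq(design, logy, rcond=None)
    return MonomialModel(
        beta0=float(coef[0]),
        exponents=dict(zip(names, (float(b) for b in coef[1:]))),
    )


def predict_monomial(model: MonomialModel, pi_features: pd.DataFrame) -> np.ndarray:
    """exp(beta0) * prod_i pi_i^beta_i per row."""
    if isinstance(pi_features, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in pi_features.columns]
        if missing:
            raise ValueError(f"missing pi column(s): {missing}")
        x = pi_features[model.feature_names]
    else:
        x = pd.DataFrame(np.asarray(pi_features, dtype=float), columns=model.feature_names)
    logx = _positive_log(x, "pi features")
    beta = np.array([model.exponents[c] for c in model.feature_names])
    return np.exp(model.beta0 + logx @ beta)


# ---------------------------------------------------------------------------
# feedforward neural network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FFNNConfig:
    """Two-hidden-layer feedforward network protocol.

    Hidden widths 64/32, Adam at learning rate 1e-3, L2 penalty 1e-4,
    mini-batches of 32, up to 1000 epochs with early stopping (patience
    50 on validation MSE), 5-fold cross-validation, 7 seeds.  All values
    are configurable; widths/epochs are package defaults.
    """

    hidden: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-3
    l2: float = 1e-4
    max_epochs: int = 1000
    batch_size: int = 32
    patience: int = 50
    n_folds: int = 5
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        if len(self.hidden) != 2:
            raise ValueError("exactly two hidden layers required")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


class _Divergence(RuntimeError):
    pass


def _new_net(config: FFNNConfig, seed: int, n_rows: int) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=config.hidden,
        activation="relu",
        solver="adam",
        alpha=config.l2,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, n_rows),
        max_iter=1,
        warm_start=True,
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=10**9,
    )


def _mse_mae(model, x, y) -> tuple[float, float]:
    p = model.predict(x)
    err = p - y
    return float(np.mean(err**2)), float(np.mean(np.abs(err)))


def _fit_epochs(
    x: np.ndarray,
    y: np.ndarray,
    config: FFNNConfig,
    seed: int,
    max_epochs: int,
    xval: np.ndarray | None = None,
    yval: np.ndarray | None = None,
) -> tuple[MLPRegressor, list[dict], int]:
    """Train epoch by epoch (warm start), recording traces.

    With a validation set, stops once validation MSE has not improved for
    ``config.patience`` epochs; returns the epoch with the best
    validation MSE (or the last epoch when no validation set is given).
    """
    net = _new_net(config, seed, len(x))
    trace: list[dict] = []
    best_val = np.inf
    best_epoch = 0
    stale = 0
    for epoch in range(1, max_epochs + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(x, y)
        train_mse, train_mae = _mse_mae(net, x, y)
        if not np.isfinite(train_mse):
            raise _Divergence(f"non-finite training loss at epoch {epoch}")
        row = {"epoch": epoch, "train_mse": train_mse, "train_mae": train_mae}
        if xval is not None:
            val_mse, val_mae = _mse_mae(net, xval, yval)
            row["val_mse"] = val_mse
            row["val_mae"] = val_mae
            if val_mse < best_val:
                best_val, best_epoch, stale = val_mse, epoch, 0
            else:
                stale += 1
            trace.append(row)
            if stale >= config.patience:
                break
        else:
            best_epoch = epoch
            trace.append(row)
    return net, trace, best_epoch


@dataclass
class FFNNResult:
    """Per-seed final models plus cross-validation traces.

    ``traces`` has one row per (seed, fold, epoch) with train/validation
    MSE and MAE; fold -1 marks the final refit on all training rows.
    ``failures`` records seeds aborted on divergent (non-finite) loss.
    """

    models: dict[int, MLPRegressor] = field(default_factory=dict)
    traces: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_epochs: dict[int, list[int]] = field(default_factory=dict)
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def seeds(self) -> list[int]:
        return list(self.models)

    def predict(self, features, seed: int) -> np.ndarray:
        return self.models[seed].predict(np.asarray(features, dtype=float))


def train_ffnn(features, targets, config: FFNNConfig | None = None) -> FFNNResult:
    """Cross-validated, multi-seed training of the feedforward network.

    For each seed: 5-fold CV with per-epoch traces and early stopping per
    fold, then a final refit on all rows for the median best epoch found
    across folds.  Features are expected standardized upstream.
    """
    config = config or FFNNConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature/target length mismatch")
    result = FFNNResult()
    all_traces: list[pd.DataFrame] = []
    for seed in config.seeds:
        try:
            fold_best: list[int] = []
            if config.n_folds >= 2:
                kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
                for fold, (tr, va) in enumerate(kf.split(x)):
                    _, trace, best = _fit_epochs(
                        x[tr], y[tr], config, seed, config.max_epochs, x[va], y[va]
                    )
                    fold_best.append(max(best, 1))
                    t = pd.DataFrame(trace)
                    t.insert(0, "fold", fold)
                    t.insert(0, "seed", seed)
                    all_traces.append(t)
                refit_epochs = int(np.median(fold_best))
            else:
                refit_epochs = config.max_epochs
            final, trace, _ = _fit_epochs(x, y, config, seed, refit_epochs)
            t = pd.DataFrame(trace)
            t.insert(0, "fold", -1)
            t.insert(0, "seed", seed)
            all_traces.append(t)
            result.models[seed] = final
            result.best_epochs[seed] = fold_best
        except _Divergence as exc:
            result.failures.append((seed, str(exc)))
    if all_traces:
        result.traces = pd.concat(all_traces, ignore_index=True)
    return result


# ---------------------------------------------------------------------------
# conventional regressor families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleConfig:
    """Fixed hyperparameters for the four regressor families.

    ridge: alpha grid logarithmically spaced 1e-3..1e10 chosen by 5-fold
    CV on MSE, no separately fitted offset (features are standardized);
    gbr: 100 estimators, learning rate 0.1, seed 42; rfr: 100 estimators,
    seed 42; svr: RBF kernel, C=1.0, epsilon=0.1.
    """

    kind: str = "ridge"
    ridge_alphas: tuple[float, ...] = tuple(np.logspace(-3, 10, 14))
    n_estimators: int = 100
    gbr_learning_rate: float = 0.1
    tree_seed: int = 42
    svr_c: float = 1.0
    svr_epsilon: float = 0.1

    def __post_init__(self) -> None:
        kinds = ("ridge", "gbr", "rfr", "svr")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}, got {self.kind!r}")


def train_ensemble(features, targets, config: EnsembleConfig):
    """Fit one of the four regressor families; returns the fitted estimator."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if x.size == 0 or x.shape[1] == 0:
        raise ValueError("empty feature set")
    if config.kind == "ridge":
        model = RidgeCV(
            alphas=config.ridge_alphas,
            fit_intercept=False,
            cv=KFold(n_splits=5),
            scoring="neg_mean_squared_error",
        )
    elif config.kind == "gbr":
        model = GradientBoostingRegressor(
            n_estimators=config.n_estimators,
            learning_rate=config.gbr_learning_rate,
            random_state=config.tree_seed,
        )
    elif config.kind == "rfr":
        model = RandomForestRegressor(
            n_estimators=config.n_estimators, random_state=config.tree_seed
        )
    else:
        model = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon)
    model.fit(x, y)
    return model


def back_transform(pi_pred, ic_org) -> np.ndarray:
    """Dimensional effluent carbon: EC_org = pi_pred * IC_org per row."""
    p = np.asarray(pi_pred, dtype=float).ravel()
    ic = np.asarray(ic_org, dtype=float).ravel()
    if p.shape != ic.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} predictions vs {ic.shape[0]} IC_org values")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite prediction")
    if np.any(ic <= 0):
        raise ValueError("IC_org must be strictly positive")
    return p * ic
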