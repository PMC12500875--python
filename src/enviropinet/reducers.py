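"""Data-driven dimensionality-reduction baselines (PCA, kernel PCA,
autoencoder), each mapping the standardized raw variables to 4 features —
the same count as the physics-derived pi-groups they are benchmarked
against.

All reducers obey a strict fit/transform separation: parameters are
estimated on training data only and ``transform`` is deterministic given
the fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import PCA, KernelPCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

__all__ = ["Reducer", "fit_pca", "fit_kpca", "fit_autoencoder", "transform"]


@dataclass
class Reducer:
    """A fitted reducer: ``kind`` in {"pca", "kpca", "autoencoder"}."""

    kind: str
    model: Any
    k: int
    info: dict = field(default_factory=dict)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def fit_pca(train_features, k: int = 4) -> Reducer:
    """Principal component analysis retaining the first ``k`` components.

    Expects features standardized upstream; errors when ``k`` exceeds the
    numerical rank of the training matrix.
    """
    x = _as_array(train_features)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds feature rank {rank}")
    model = PCA(n_components=k, svd_solver="full")
    model.fit(x)
    return Reducer(kind="pca", model=model, k=k)


def fit_kpca(train_features, k: int = 4, kernel: str = "rbf", gamma=None) -> Reducer:
    """Kernel PCA with an RBF kernel (bandwidth 1/n_features by default)."""
    x = _as_array(train_features)
    model = KernelPCA(n_components=k, kernel=kernel, gamma=gamma, random_state=0)
    model.fit(x)
    return Reducer(kind="kpca", model=model, k=k, info={"kernel": kernel})


def fit_autoencoder(
    train_features,
    bottleneck: int = 4,
    seed: int = 0,
    hidden: int = 6,
    max_epochs: int = 500,
) -> Reducer:
    """Symmetric autoencoder (d -> hidden -> bottleneck -> hidden -> d).

    ReLU hidden layers, linear output, Adam on MSE reconstruction loss,
    with early stopping on an internal validation fold.  Failure to
    converge within ``max_epochs`` is recorded as a warning in the
    returned reducer, never raised.
    """
    x = _as_array(train_features)
    if x.shape[1] < bottleneck:
        raise ValueError(
            f"need >= {bottleneck} input features, got {x.shape[1]}"
        )
    net = MLPRegressor(
        hidden_layer_sizes=(hidden, bottleneck, hidden),
        activation="relu",
        solver="adam",
        alpha=1e-4,
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=20,
        random_state=seed,
    )
    info: dict = {"seed": seed, "converged": True}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        net.fit(x, x)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        info["converged"] = False
        info["warning"] = f"autoencoder did not converge within {max_epochs} epochs"
        warnings.warn(info["warning"], stacklevel=2)
    # encoder = layers up to and including the bottleneck
    info["n_encoder_layers"] = 2
    info["loss_curve"] = list(net.loss_curve_)
    return Reducer(kind="autoencoder", model=net, k=bottleneck, info=info)


def _encode(net: MLPRegressor, x: np.ndarray, n_layers: int) -> np.ndarray:
    a = x
    for i in range(n_layers):
        a = a @ net.coefs_[i] + net.intercepts_[i]
        a = np.maximum(a, 0.0)  # ReLU hidden activations
    return a


def transform(reducer: Reducer, features) -> np.ndarray:
    """Map features into the reduced ``k``-dimensional space."""
    x = _as_array(features)
    if reducer.kind in ("pca", "kpca"):
        return reducer.model.transform(x)
    if reducer.kind == "autoencoder":
        return _encode(reducer.model, x, reducer.info["n_encoder_layers"])
    raise ValueError(f"unknown reducer kind {reducer.kind!r}")
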