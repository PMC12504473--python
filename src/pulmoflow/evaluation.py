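"""Evaluation protocols: metrics, cross-validation, grid search, cost model.

Metric conventions
------------------
The coefficient of determination is ``R^2 = 1 - RSS/TSS`` with both sums of
squares normalized by the sample count; it equals 1 for perfect predictions
and can be arbitrarily negative.  MAE and RMSE use the same N-normalized
convention.  Surrogate selection scores the first principal component (PC1)
of ux, the component carrying most of the explained variance; per-quantity
test reports pool all retained components.

Spatial accuracy at the peak-inspiration instant uses the per-node relative
error in percent, ``100 |z - zhat| / max(|z|, floor)``, evaluated at a
reproducible random subset of landmark nodes.  The floor guards nodes whose
true value is near zero (e.g. displacements near the shell axis crossing);
it defaults to 1e-6 times the field's maximum magnitude.

The equivalent high-fidelity training cost expresses the mixed-fidelity
data expense in units of HF simulations:

    C_eq = C_H + C_L,   C_H = N_H,   C_L = N_L * T_L / T_H,

with T_L, T_H the mean per-simulation wall times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pulmoflow.mfnn import (
    MultiFidelityRegression,
    SingleFidelityRegression,
    TrainingConfig,
)

__all__ = [
    "r2_score",
    "mae",
    "rmse",
    "relative_error_at_peak",
    "sample_landmarks",
    "CostReport",
    "equivalent_cost",
    "kfold_indices",
    "cross_validate",
    "HyperparameterGrid",
    "grid_search",
]


def r2_score(y, yhat) -> float:
    """Coefficient of determination 1 - RSS/TSS (N-normalized sums)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two samples")
    tss = np.mean((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant truth vector: TSS undefined")
    rss = np.mean((y - yhat) ** 2)
    return float(1.0 - rss / tss)


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error (N-normalized)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def sample_landmarks(K: int, n: int = 100, seed: int = 0) -> np.ndarray:
    """Reproducible random landmark node indices (without replacement)."""
    if n > K:
        raise ValueError("cannot sample more landmarks than nodes")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(K, size=n, replace=False))


def relative_error_at_peak(z_true, z_pred, floor: float | None = None) -> np.ndarray:
    """Per-node relative error in percent at the peak-inspiration snapshot.

    ``100 |z - zhat| / max(|z|, floor)``.  ``floor`` defaults to 1e-6 times
    the maximum field magnitude; an identically zero truth field with a
    zero floor is rejected.
    """
    z_true = np.asarray(z_true, dtype=float).ravel()
    z_pred = np.asarray(z_pred, dtype=float).ravel()
    if z_true.size != z_pred.size:
        raise ValueError("node count mismatch")
    zmax = np.max(np.abs(z_true))
    if floor is None:
        floor = 1e-6 * zmax
    if zmax == 0 and floor <= 0:
        raise ValueError("all-zero truth field with zero floor")
    denom = np.maximum(np.abs(z_true), floor)
    return 100.0 * np.abs(z_true - z_pred) / denom


# --------------------------------------------------------------------------
# training-cost model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CostReport:
    """Equivalent high-fidelity training cost of a mixed dataset."""

    N_H: int
    N_L: int
    T_L: float  # mean LF simulation time (minutes)
    T_H: float  # mean HF simulation time (minutes)

    @property
    def C_H(self) -> float:
        return float(self.N_H)

    @property
    def C_L(self) -> float:
        return self.N_L * self.T_L / self.T_H

    @property
    def C_eq(self) -> float:
        return self.C_H + self.C_L

    def summary(self) -> str:
        return (
            f"N_H={self.N_H}, N_L={self.N_L}, T_L={self.T_L:.2f} min, "
            f"T_H={self.T_H:.2f} min -> C_H={self.C_H:.2f}, "
            f"C_L={self.C_L:.2f}, C_eq={self.C_eq:.2f}"
        )


def equivalent_cost(N_H: int, N_L: int, T_L: float, T_H: float) -> CostReport:
    """Exact cost arithmetic; rounding happens only at report formatting."""
    if N_H < 0 or N_L < 0:
        raise ValueError("sample counts must be >= 0")
    if T_H <= 0:
        raise ValueError("T_H must be > 0")
    return CostReport(N_H=int(N_H), N_L=int(N_L), T_L=float(T_L), T_H=float(T_H))


# --------------------------------------------------------------------------
# cross-validation and grid search
# --------------------------------------------------------------------------


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into ``folds`` validation sets."""
    if folds < 2 or n // folds < 1:
        raise ValueError("invalid fold count")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(
    X_high,
    y_high,
    fit_fn,
    *,
    folds: int = 3,
    seed: int = 0,
    component: int = 0,
) -> tuple[float, float, list[float]]:
    """K-fold cross-validation scored by R^2 of one score component.

    ``fit_fn(X_train, y_train)`` must return an object with
    ``predict(X) -> (n, k)``; for multi-fidelity models the LF dataset is
    closed over by the caller and used in full within every fold.  Returns
    (mean, sample sd, per-fold scores), scored on the component ``component``
    (PC1 by default) of the validation predictions.

    Fold assignment is a seeded random permutation, with disjoint validation
    folds covering the training set.
    """
    X_high = np.atleast_2d(np.asarray(X_high, dtype=float))
    y_high = np.atleast_2d(np.asarray(y_high, dtype=float))
    n = X_high.shape[0]
    parts = kfold_indices(n, folds, seed)
    scores = []
    for val_idx in parts:
        if val_idx.size < 2:
            raise ValueError("validation fold smaller than 2 samples")
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        fitted = fit_fn(X_high[train_idx], y_high[train_idx])
        pred = np.atleast_2d(fitted.predict(X_high[val_idx]))
        scores.append(r2_score(y_high[val_idx][:, component], pred[:, component]))
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return mean, sd, scores


@dataclass(frozen=True)
class HyperparameterGrid:
    """The HF-subnet search grid (lambda tied across both HF subnets)."""

    lambdas: tuple[float, ...] = (1e-1, 1e-3)
    n_neurons: tuple[int, ...] = (30, 60)
    n_layers: tuple[int, ...] = (3, 6)
    activations: tuple[str, ...] = ("tanh", "relu")

    def combinations(self) -> list[dict]:
        combos = []
        for ilam, lam in enumerate(self.lambdas):
            for nn, nl, act in itertools.product(self.n_neurons, self.n_layers, self.activations):
                combos.append(
                    {
                        "reg_lambda": lam,
                        "n_neurons": nn,
                        "n_layers": nl,
                        "activation": act,
                        "_lambda_index": ilam,
                    }
                )
        if not combos:
            raise ValueError("empty hyperparameter grid")
        return combos


def _count_params(hp: dict, d: int, k_low: int, k_high: int, mode: str) -> int:
    nn, nl = hp["n_neurons"], hp["n_layers"]

    def chain(dims):
        return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))

    if mode == "sf":
        return chain([d] + [nn] * nl + [k_high])
    hf = chain([d + k_low] + [nn] * nl + [k_high])
    low = chain([d] + [60] * 5 + [k_low])
    return low + 2 * hf


def grid_search(
    X_high,
    y_high,
    *,
    mode: str = "mf",
    X_low=None,
    y_low=None,
    grid: HyperparameterGrid | None = None,
    folds: int = 3,
    seed: int = 0,
    config: TrainingConfig | None = None,
    scale_targets: bool = True,
    model_factory=None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search by k-fold cross-validation on PC1.

    Evaluates every combination of the grid (16 by default), selecting the
    highest mean validation R^2; ties break to fewer total parameters, then
    to the lower index in the lambda list.  Returns the winning
    hyperparameters and a leaderboard sorted by decreasing mean R^2.

    ``model_factory(hp, X_train, y_train)`` may override model construction
    (used in tests to inject oracles); it must return an object with
    ``fit(config) -> results`` or ``predict``.
    """
    grid = grid or HyperparameterGrid()
    config = config or TrainingConfig()
    X_high = np.atleast_2d(np.asarray(X_high, dtype=float))
    y_high = np.atleast_2d(np.asarray(y_high, dtype=float))
    if mode == "mf":
        if X_low is None or y_low is None:
            raise ValueError("multi-fidelity grid search needs the LF dataset")
        X_low = np.atleast_2d(np.asarray(X_low, dtype=float))
        y_low = np.atleast_2d(np.asarray(y_low, dtype=float))
        k_low = y_low.shape[1]
    elif mode == "sf":
        k_low = 0
    else:
        raise ValueError("mode must be 'mf' or 'sf'")

    rows = []
    for hp in grid.combinations():
        kwargs = {k: hp[k] for k in ("reg_lambda", "n_neurons", "n_layers", "activation")}

        def build(Xtr, ytr, _kw=kwargs):
            if model_factory is not None:
                return model_factory(_kw, Xtr, ytr)
            if mode == "mf":
                return MultiFidelityRegression(
                    X_low, y_low, Xtr, ytr, scale_targets=scale_targets, **_kw
                )
            return SingleFidelityRegression(Xtr, ytr, scale_targets=scale_targets, **_kw)

        def fit_fn(Xtr, ytr):
            model = build(Xtr, ytr)
            return model.fit(config) if hasattr(model, "fit") else model

        mean, sd, scores = cross_validate(X_high, y_high, fit_fn, folds=folds, seed=seed)
        rows.append(
            dict(
                **{k: hp[k] for k in ("reg_lambda", "n_neurons", "n_layers", "activation")},
                mean_r2=mean,
                sd_r2=sd,
                n_params=_count_params(hp, X_high.shape[1], k_low, y_high.shape[1], mode),
                _lambda_index=hp["_lambda_index"],
            )
        )
    board = pd.DataFrame(rows)
    board = board.sort_values(
        by=["mean_r2", "n_params", "_lambda_index"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = board.iloc[0]
    best_hp = {
        "reg_lambda": float(best["reg_lambda"]),
        "n_neurons": int(best["n_neurons"]),
        "n_layers": int(best["n_layers"]),
        "activation": str(best["activation"]),
    }
    return best_hp, board.drop(columns=["_lambda_index"])
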