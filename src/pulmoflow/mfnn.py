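"""Composite multi-fidelity neural-network surrogates on reduced scores.

The surrogate predicts truncated principal-component scores of a simulated
quantity from the 7 model parameters.  The multi-fidelity architecture is a
composite of three fully connected networks trained jointly:

* ``NN_L(x)``: learns the low-fidelity scores from abundant LF data and
  acts as the baseline trend model;
* ``NN_H1(x || y_L)``: contains no activation functions (affine end to
  end) and captures the *linear* correlation between LF and HF scores;
* ``NN_H2(x || y_L)``: a standard nonlinear network capturing the
  remaining nonlinear correlation.

The high-fidelity prediction is the sum ``y_H = NN_H1 + NN_H2``, and all
three parameter sets minimize one combined loss

    L = MSE_L + MSE_H + lam_L |theta_L|^2 + lam_H1 |theta_H1|^2
        + lam_H2 |theta_H2|^2,

where each MSE averages squared errors over samples and output components.
The single-fidelity baseline keeps only the nonlinear subnet and trains on
HF data alone.

Optimization is full-batch Adam (the datasets hold at most a few hundred
rows), deterministic for a fixed seed.  Inputs are standardized to zero
mean and unit (population) standard deviation.  Score targets are
standardized per component inside the model and predictions are mapped
back to the original score scale; this keeps the optimizer's effective
step size commensurate with targets whose magnitudes span orders of
magnitude across quantities (disable with ``scale_targets=False``).

Everything is plain numpy: forward/backward passes for the composite are
written out explicitly, with all weights of the three subnets stored in a
single flat parameter vector so the Adam update is one vectorized
operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TrainingConfig",
    "SubnetHyperparams",
    "Standardizer",
    "standardize",
    "mse",
    "TrainingError",
    "MultiFidelityRegression",
    "MultiFidelityResults",
    "SingleFidelityRegression",
    "SingleFidelityResults",
]


class TrainingError(RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings (full-batch Adam)."""

    learning_rate: float = 1e-3
    epochs: int = 5000
    seed: int = 0
    optimizer: str = "adam"
    pretrain_low_epochs: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("need learning_rate > 0 and epochs >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass(frozen=True)
class SubnetHyperparams:
    """Width/depth/regularization of one subnet."""

    reg_lambda: float
    n_neurons: int
    n_layers: int
    activation: str  # 'tanh' | 'relu' | 'none'

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_neurons < 1 or self.reg_lambda < 0:
            raise ValueError("invalid subnet hyperparameters")
        if self.activation not in ("tanh", "relu", "none"):
            raise ValueError("activation must be 'tanh', 'relu' or 'none'")


# --------------------------------------------------------------------------
# input standardization
# --------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-feature zero-mean unit-sd scaling (population sd, ddof = 0)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a standardizer")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s) {zero.tolist()}: cannot standardize")
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.sd

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) * self.sd + self.mean


def standardize(X: np.ndarray, stats: Standardizer | None = None):
    """Standardize columns of X; fit stats when none are given.

    Returns ``(X_standardized, stats)``.
    """
    if stats is None:
        stats = Standardizer.fit(X)
    return stats.transform(X), stats


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error averaged over samples and output components."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((y - yhat) ** 2))


# --------------------------------------------------------------------------
# flat-parameter multilayer perceptron
# --------------------------------------------------------------------------


class _MLP:
    """Fully connected net whose parameters live in a flat vector segment.

    ``dims = [d_in, hidden..., d_out]``; hidden layers carry the activation,
    the output layer is always linear, so ``activation='none'`` makes the
    whole net affine.
    """

    def __init__(self, dims: list[int], activation: str):
        self.dims = list(dims)
        self.activation = activation
        self.shapes = [(dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.n_params = sum(din * dout + dout for din, dout in self.shapes)

    def views(self, flat: np.ndarray):
        out = []
        o = 0
        for din, dout in self.shapes:
            W = flat[o : o + din * dout].reshape(din, dout)
            o += din * dout
            b = flat[o : o + dout]
            o += dout
            out.append((W, b))
        return out

    def init(self, flat: np.ndarray, rng: np.random.Generator) -> None:
        # uniform fan-in scheme: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        for W, b in self.views(flat):
            bound = 1.0 / np.sqrt(W.shape[0])
            W[...] = rng.uniform(-bound, bound, W.shape)
            b[...] = rng.uniform(-bound, bound, b.shape)

    def forward(self, params, X):
        h = X
        cache = []
        last = len(params) - 1
        for i, (W, b) in enumerate(params):
            z = h @ W + b
            if i < last and self.activation == "tanh":
                a = np.tanh(z)
            elif i < last and self.activation == "relu":
                a = np.maximum(z, 0.0)
            else:
                a = z
            cache.append((h, a))
            h = a
        return h, cache

    def backward(self, params, cache, grad_out, grad_flat):
        """Backpropagate; accumulates parameter grads, returns dL/dX."""
        g = grad_out
        gviews = self.views(grad_flat)
        last = len(params) - 1
        for i in range(last, -1, -1):
            h, a = cache[i]
            if i < last and self.activation == "tanh":
                gz = g * (1.0 - a * a)
            elif i < last and self.activation == "relu":
                gz = g * (a > 0.0)
            else:
                gz = g
            W, _ = params[i]
            gW, gb = gviews[i]
            gW += h.T @ gz
            gb += gz.sum(axis=0)
            g = gz @ W.T
        return g


class _Adam:
    def __init__(self, n: int, lr: float):
        self.lr = lr
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m += (1 - self.b1) * (grad - self.m)
        self.v += (1 - self.b2) * (grad * grad - self.v)
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class _TargetScaler:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, Y: np.ndarray, enabled: bool) -> "_TargetScaler":
        Y = np.atleast_2d(Y)
        if not enabled:
            return cls(mean=np.zeros(Y.shape[1]), sd=np.ones(Y.shape[1]))
        sd = Y.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=Y.mean(axis=0), sd=sd)

    def transform(self, Y):
        return (Y - self.mean) / self.sd

    def inverse(self, Y):
        return Y * self.sd + self.mean


# --------------------------------------------------------------------------
# multi-fidelity model
# --------------------------------------------------------------------------


class MultiFidelityRegression:
    """Joint regression of HF principal-component scores from parameters.

    Parameters
    ----------
    X_low, y_low : (N_L, d), (N_L, k_L)
        Low-fidelity inputs and score targets (N_L abundant).
    X_high, y_high : (N_H, d), (N_H, k_H)
        High-fidelity training pairs (N_H scarce, N_H <= N_L).
    reg_lambda : float
        Tied L2 rate of the two high-fidelity subnets (lam_H1 = lam_H2).
    n_neurons, n_layers, activation
        Architecture of the HF subnets; the activation also applies to the
        LF subnet, while ``NN_H1`` never has one.
    low_hyperparams : SubnetHyperparams, optional
        The LF subnet (default lambda 1e-3, 60 neurons, 5 layers).
    scale_targets : bool
        Standardize score targets internally (see module docstring).
    """

    def __init__(
        self,
        X_low,
        y_low,
        X_high,
        y_high,
        *,
        reg_lambda: float = 1e-3,
        n_neurons: int = 60,
        n_layers: int = 6,
        activation: str = "tanh",
        low_hyperparams: SubnetHyperparams | None = None,
        scale_targets: bool = True,
    ):
        self.X_low = np.atleast_2d(np.asarray(X_low, dtype=float))
        self.y_low = np.atleast_2d(np.asarray(y_low, dtype=float))
        self.X_high = np.atleast_2d(np.asarray(X_high, dtype=float))
        self.y_high = np.atleast_2d(np.asarray(y_high, dtype=float))
        if self.X_low.shape[0] != self.y_low.shape[0]:
            raise ValueError("X_low and y_low row mismatch")
        if self.X_high.shape[0] != self.y_high.shape[0]:
            raise ValueError("X_high and y_high row mismatch")
        if self.X_high.shape[0] < 2:
            raise ValueError("need at least 2 high-fidelity samples")
        if self.X_low.shape[0] < self.X_high.shape[0]:
            raise ValueError("the multi-fidelity regime requires N_L >= N_H")
        if self.X_low.shape[1] != self.X_high.shape[1]:
            raise ValueError("LF and HF inputs must share the feature space")

        d = self.X_low.shape[1]
        self.k_low = self.y_low.shape[1]
        self.k_high = self.y_high.shape[1]
        lo = low_hyperparams or SubnetHyperparams(1e-3, 60, 5, activation)
        self.hp_low = lo
        self.hp_high = SubnetHyperparams(reg_lambda, n_neurons, n_layers, activation)
        self.scale_targets = scale_targets

        self.net_low = _MLP([d] + [lo.n_neurons] * lo.n_layers + [self.k_low], lo.activation)
        dims_h = [d + self.k_low] + [n_neurons] * n_layers + [self.k_high]
        self.net_lin = _MLP(dims_h, "none")
        self.net_nl = _MLP(dims_h, activation)

        self.n_params = self.net_low.n_params + self.net_lin.n_params + self.net_nl.n_params
        o1 = self.net_low.n_params
        o2 = o1 + self.net_lin.n_params
        self._slices = (slice(0, o1), slice(o1, o2), slice(o2, self.n_params))
        self._lambda_vec = np.concatenate(
            [
                np.full(self.net_low.n_params, lo.reg_lambda),
                np.full(self.net_lin.n_params, reg_lambda),
                np.full(self.net_nl.n_params, reg_lambda),
            ]
        )

        self.standardizer = Standardizer.fit(np.vstack([self.X_low, self.X_high]))
        self._Xl = self.standardizer.transform(self.X_low)
        self._Xh = self.standardizer.transform(self.X_high)
        self._X_all = np.vstack([self._Xl, self._Xh])
        self.scaler_low = _TargetScaler.fit(self.y_low, scale_targets)
        self.scaler_high = _TargetScaler.fit(self.y_high, scale_targets)
        self._yl_t = self.scaler_low.transform(self.y_low)
        self._yh_t = self.scaler_high.transform(self.y_high)

    # -- parameter plumbing -------------------------------------------------

    def initialize(self, seed: int = 0) -> np.ndarray:
        theta = np.empty(self.n_params)
        rng = np.random.default_rng(seed)
        self.net_low.init(theta[self._slices[0]], rng)
        self.net_lin.init(theta[self._slices[1]], rng)
        self.net_nl.init(theta[self._slices[2]], rng)
        return theta

    def _views(self, theta):
        return (
            self.net_low.views(theta[self._slices[0]]),
            self.net_lin.views(theta[self._slices[1]]),
            self.net_nl.views(theta[self._slices[2]]),
        )

    def _forward_high(self, theta, Xs):
        pl, p1, p2 = self._views(theta)
        yl, _ = self.net_low.forward(pl, Xs)
        v = np.hstack([Xs, yl])
        o1, _ = self.net_lin.forward(p1, v)
        o2, _ = self.net_nl.forward(p2, v)
        return yl, o1, o2

    def loss(self, theta: np.ndarray) -> float:
        """Combined regularized loss at parameters ``theta`` (scaled space)."""
        pl, p1, p2 = self._views(theta)
        yl_all, _ = self.net_low.forward(pl, self._X_all)
        NL = self._Xl.shape[0]
        v = np.hstack([self._Xh, yl_all[NL:]])
        o1, _ = self.net_lin.forward(p1, v)
        o2, _ = self.net_nl.forward(p2, v)
        value = mse(self._yl_t, yl_all[:NL]) + mse(self._yh_t, o1 + o2)
        return value + self.penalty(theta)

    def penalty(self, theta: np.ndarray) -> float:
        """The L2 term lam_L |th_L|^2 + lam_H1 |th_H1|^2 + lam_H2 |th_H2|^2."""
        return float(np.sum(self._lambda_vec * theta**2))

    # -- training -----------------------------------------------------------

    def fit(self, config: TrainingConfig | None = None) -> "MultiFidelityResults":
        config = config or TrainingConfig()
        theta = self.initialize(config.seed)
        grad = np.zeros_like(theta)
        adam = _Adam(self.n_params, config.learning_rate)
        NL = self._Xl.shape[0]
        loss_trace = np.empty(config.epochs + config.pretrain_low_epochs)

        pl, p1, p2 = self._views(theta)
        gl = grad[self._slices[0]]
        g1 = grad[self._slices[1]]
        g2 = grad[self._slices[2]]

        if config.pretrain_low_epochs:
            # optional staged start: optimize NN_L alone on the LF loss
            adam_lo = _Adam(self.net_low.n_params, config.learning_rate)
            th_lo = theta[self._slices[0]]
            lam_lo = self._lambda_vec[self._slices[0]]
            for ep in range(config.pretrain_low_epochs):
                gl[:] = 0.0
                yl, cache = self.net_low.forward(pl, self._Xl)
                e = yl - self._yl_t
                self.net_low.backward(pl, cache, 2.0 * e / e.size, gl)
                gl += 2.0 * lam_lo * th_lo
                loss_trace[ep] = mse(self._yl_t, yl) + float(np.sum(lam_lo * th_lo**2))
                adam_lo.step(th_lo, gl)

        off = config.pretrain_low_epochs
        d = self._Xh.shape[1]
        for ep in range(config.epochs):
            grad[:] = 0.0
            yl_all, cache_l = self.net_low.forward(pl, self._X_all)
            v = np.hstack([self._Xh, yl_all[NL:]])
            o1, cache_1 = self.net_lin.forward(p1, v)
            o2, cache_2 = self.net_nl.forward(p2, v)
            e_l = yl_all[:NL] - self._yl_t
            e_h = (o1 + o2) - self._yh_t
            loss_ep = (
                float(np.mean(e_l**2))
                + float(np.mean(e_h**2))
                + float(np.sum(self._lambda_vec * theta**2))
            )
            loss_trace[off + ep] = loss_ep
            if not np.isfinite(loss_ep):
                raise TrainingError(f"non-finite loss at epoch {ep}", ep)

            g_h = 2.0 * e_h / e_h.size
            gv = self.net_lin.backward(p1, cache_1, g_h, g1)
            gv = gv + self.net_nl.backward(p2, cache_2, g_h, g2)
            g_all = np.vstack([2.0 * e_l / e_l.size, gv[:, d:]])
            self.net_low.backward(pl, cache_l, g_all, gl)
            grad += 2.0 * self._lambda_vec * theta
            adam.step(theta, grad)

        return MultiFidelityResults(model=self, params=theta, config=config, loss_trace=loss_trace)


@dataclass
class MultiFidelityResults:
    """Fitted composite surrogate.

    ``predict`` returns HF scores on the original score scale; the additive
    decomposition of the prediction into the linear (NN_H1) and nonlinear
    (NN_H2) subnet outputs is exposed by :meth:`predict_components` in the
    model's internal (scaled) target space, with
    ``predict(x) = scaler_high.inverse(sum of components)``.
    """

    model: MultiFidelityRegression
    params: np.ndarray
    config: TrainingConfig
    loss_trace: np.ndarray

    def _check(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X_high.shape[1]:
            raise ValueError("wrong input width")
        return X

    def _forward(self, X):
        Xs = self.model.standardizer.transform(self._check(X))
        return self.model._forward_high(self.params, Xs)

    def predict(self, X) -> np.ndarray:
        """Predicted HF scores, shape (n, k_H)."""
        _, o1, o2 = self._forward(X)
        return self.model.scaler_high.inverse(o1 + o2)

    def predict_low(self, X) -> np.ndarray:
        """The LF subnet's score prediction, shape (n, k_L)."""
        yl, _, _ = self._forward(X)
        return self.model.scaler_low.inverse(yl)

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(linear, nonlinear) subnet outputs in the scaled target space."""
        _, o1, o2 = self._forward(X)
        return o1, o2

    def predict_field(self, X, basis) -> np.ndarray:
        """Reconstruct full HF spatiotemporal fields from predicted scores.

        Returns an array of shape (n, K, T) for the basis' quantity.
        """
        from pulmoflow.reduction import reconstruct

        scores = self.predict(X)
        if scores.shape[1] != basis.k:
            raise ValueError(
                f"model predicts {scores.shape[1]} components but basis truncates at {basis.k}"
            )
        Z = reconstruct(scores, basis)
        return np.stack([Z.unflatten(row) for row in Z.values])

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multi-fidelity reduced-order surrogate (rMFNN)",
            "=" * 47,
            f"inputs: {m.X_high.shape[1]}   k_L: {m.k_low}   k_H: {m.k_high}",
            f"N_L: {m.X_low.shape[0]}   N_H: {m.X_high.shape[0]}",
            f"NN_L : {m.hp_low.n_layers} x {m.hp_low.n_neurons} ({m.hp_low.activation}), "
            f"lambda={m.hp_low.reg_lambda:g}",
            f"NN_H1: {m.hp_high.n_layers} x {m.hp_high.n_neurons} (affine), "
            f"lambda={m.hp_high.reg_lambda:g}",
            f"NN_H2: {m.hp_high.n_layers} x {m.hp_high.n_neurons} ({m.hp_high.activation}), "
            f"lambda={m.hp_high.reg_lambda:g}",
            f"parameters: {m.n_params}   epochs: {self.config.epochs}   "
            f"lr: {self.config.learning_rate:g}   seed: {self.config.seed}",
            f"final loss: {self.final_loss:.6g}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist weights (npz) plus JSON metadata to a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        m = self.model
        meta = {
            "kind": "mf",
            "dims": {"d": m.X_high.shape[1], "k_low": m.k_low, "k_high": m.k_high},
            "hp_low": vars(m.hp_low) | {},
            "hp_high": vars(m.hp_high) | {},
            "scale_targets": m.scale_targets,
            "config": {
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
            },
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2, default=str))
        np.savez(
            d / "weights.npz",
            params=self.params,
            loss_trace=self.loss_trace,
            x_mean=m.standardizer.mean,
            x_sd=m.standardizer.sd,
            yl_mean=m.scaler_low.mean,
            yl_sd=m.scaler_low.sd,
            yh_mean=m.scaler_high.mean,
            yh_sd=m.scaler_high.sd,
        )


# --------------------------------------------------------------------------
# single-fidelity baseline
# --------------------------------------------------------------------------


class SingleFidelityRegression:
    """Reduced-order single-fidelity baseline (rSFNN).

    Equivalent to keeping only the nonlinear subnet of the composite
    architecture, with the model parameters as its only input, trained on
    high-fidelity data alone.
    """

    def __init__(
        self,
        X_high,
        y_high,
        *,
        reg_lambda: float = 1e-1,
        n_neurons: int = 30,
        n_layers: int = 3,
        activation: str = "tanh",
        scale_targets: bool = True,
    ):
        self.X_high = np.atleast_2d(np.asarray(X_high, dtype=float))
        self.y_high = np.atleast_2d(np.asarray(y_high, dtype=float))
        if self.X_high.shape[0] != self.y_high.shape[0]:
            raise ValueError("X_high and y_high row mismatch")
        self.k_high = self.y_high.shape[1]
        self.hp = SubnetHyperparams(reg_lambda, n_neurons, n_layers, activation)
        self.scale_targets = scale_targets
        d = self.X_high.shape[1]
        self.net = _MLP([d] + [n_neurons] * n_layers + [self.k_high], activation)
        self.n_params = self.net.n_params
        self.standardizer = Standardizer.fit(self.X_high)
        self._Xh = self.standardizer.transform(self.X_high)
        self.scaler_high = _TargetScaler.fit(self.y_high, scale_targets)
        self._yh_t = self.scaler_high.transform(self.y_high)

    def initialize(self, seed: int = 0) -> np.ndarray:
        theta = np.empty(self.n_params)
        self.net.init(theta, np.random.default_rng(seed))
        return theta

    def loss(self, theta: np.ndarray) -> float:
        yh, _ = self.net.forward(self.net.views(theta), self._Xh)
        return mse(self._yh_t, yh) + self.hp.reg_lambda * float(np.sum(theta**2))

    def fit(self, config: TrainingConfig | None = None) -> "SingleFidelityResults":
        config = config or TrainingConfig()
        theta = self.initialize(config.seed)
        grad = np.zeros_like(theta)
        adam = _Adam(self.n_params, config.learning_rate)
        params = self.net.views(theta)
        loss_trace = np.empty(config.epochs)
        for ep in range(config.epochs):
            grad[:] = 0.0
            yh, cache = self.net.forward(params, self._Xh)
            e = yh - self._yh_t
            loss_ep = float(np.mean(e**2)) + self.hp.reg_lambda * float(np.sum(theta**2))
            loss_trace[ep] = loss_ep
            if not np.isfinite(loss_ep):
                raise TrainingError(f"non-finite loss at epoch {ep}", ep)
            self.net.backward(params, cache, 2.0 * e / e.size, grad)
            grad += 2.0 * self.hp.reg_lambda * theta
            adam.step(theta, grad)
        return SingleFidelityResults(model=self, params=theta, config=config, loss_trace=loss_trace)


@dataclass
class SingleFidelityResults:
    model: SingleFidelityRegression
    params: np.ndarray
    config: TrainingConfig
    loss_trace: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X_high.shape[1]:
            raise ValueError("wrong input width")
        Xs = self.model.standardizer.transform(X)
        yh, _ = self.model.net.forward(self.model.net.views(self.params), Xs)
        return self.model.scaler_high.inverse(yh)

    def predict_field(self, X, basis) -> np.ndarray:
        from pulmoflow.reduction import reconstruct

        scores = self.predict(X)
        if scores.shape[1] != basis.k:
            raise ValueError("basis/quantity mismatch")
        Z = reconstruct(scores, basis)
        return np.stack([Z.unflatten(row) for row in Z.values])

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "Single-fidelity reduced-order surrogate (rSFNN)",
                "=" * 47,
                f"inputs: {m.X_high.shape[1]}   k_H: {m.k_high}   N_H: {m.X_high.shape[0]}",
                f"net: {m.hp.n_layers} x {m.hp.n_neurons} ({m.hp.activation}), "
                f"lambda={m.hp.reg_lambda:g}",
                f"parameters: {m.n_params}   epochs: {self.config.epochs}   "
                f"seed: {self.config.seed}",
                f"final loss: {self.final_loss:.6g}",
            ]
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": "sf",
            "hp": vars(self.model.hp) | {},
            "scale_targets": self.model.scale_targets,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2, default=str))
        np.savez(
            d / "weights.npz",
            params=self.params,
            loss_trace=self.loss_trace,
            x_mean=self.model.standardizer.mean,
            x_sd=self.model.standardizer.sd,
            yh_mean=self.model.scaler_high.mean,
            yh_sd=self.model.scaler_high.sd,
        )
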