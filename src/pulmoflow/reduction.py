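"""Spatiotemporal dimensionality reduction by truncated SVD.

Each simulated quantity q (ux, uy, uz, palv) of one fidelity produces an
output matrix ``Z`` of shape (N, M) with ``M = K * T``: row n is the
time-major flattening of the (K, T) field of simulation n, i.e. the nodal
snapshot at t1 followed by the snapshot at t2, and so on.

The (uncentered) thin SVD ``Z = U S W^T`` is computed through the N x N
Gram matrix ``Z Z^T`` since N << M.  The principal-component scores are
``Y = Z W``; truncating at the smallest k whose cumulative variance ratio
``sum_{i<=k} s_i^2 / sum_i s_i^2`` reaches the threshold (0.99 by default)
gives the reduced dataset ``Y_k = Z W_k``, and fields are recovered by the
inverse map ``Z_R = Y_k W_k^T``.

No mean-centering is applied by default: the factorization acts on the raw
output matrix and only the surrogate inputs are standardized elsewhere.
Centering is available behind a flag for sensitivity checks.  Singular
vector signs are fixed so that each basis vector's largest-magnitude entry
is positive, making scores reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OutputMatrix",
    "ReducedBasis",
    "ScoreMatrix",
    "assemble_output_matrix",
    "flatten_field",
    "unflatten_field",
    "fit_reduction",
    "transform",
    "reconstruct",
]


@dataclass
class OutputMatrix:
    """N x (K*T) matrix of flattened spatiotemporal responses."""

    values: np.ndarray
    quantity: str
    fidelity: str
    K: int
    T: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.K * self.T:
            raise ValueError("OutputMatrix values must have shape (N, K*T)")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def unflatten(self, row: np.ndarray) -> np.ndarray:
        """Recover the (K, T) field from one flattened row."""
        return unflatten_field(row, self.K, self.T)


@dataclass
class ReducedBasis:
    """Truncated right-singular-vector basis of one output matrix.

    ``W_k`` is M x k with orthonormal columns; all singular values are kept
    for diagnostics.  ``k`` is the smallest integer whose cumulative
    variance ratio reaches ``threshold``.
    """

    W: np.ndarray  # M x r, all numerically nonzero components (diagnostics)
    singular_values: np.ndarray
    k: int
    threshold: float
    quantity: str
    fidelity: str
    K: int
    T: int
    centered: bool = False
    mean: np.ndarray | None = None

    @property
    def W_k(self) -> np.ndarray:
        return self.W[:, : self.k]

    @property
    def variance_ratio(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum()

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_ratio)

    def components_for(self, threshold: float) -> int:
        """Smallest k capturing at least ``threshold`` cumulative variance."""
        return int(np.searchsorted(self.cumulative_variance, threshold - 1e-12) + 1)


@dataclass
class ScoreMatrix:
    """N x k principal-component scores tied to a ReducedBasis."""

    scores: np.ndarray
    basis: ReducedBasis

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def flatten_field(field: np.ndarray) -> np.ndarray:
    """Flatten a (K, T) field time-major: column m -> (t = m // K, node = m % K)."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("field must be (K, T)")
    return field.T.reshape(-1)


def unflatten_field(row: np.ndarray, K: int, T: int) -> np.ndarray:
    row = np.asarray(row)
    if row.size != K * T:
        raise ValueError("row length must be K*T")
    return row.reshape(T, K).T


def assemble_output_matrix(responses, quantity: str) -> OutputMatrix:
    """Stack the flattened ``quantity`` fields of N simulations row-wise.

    All responses must share the node cloud size, time grid, and fidelity.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("need at least one response")
    K, T = responses[0].K, responses[0].T
    fidelity = responses[0].fidelity
    rows = []
    for r in responses:
        if (r.K, r.T, r.fidelity) != (K, T, fidelity):
            raise ValueError("mixed response shapes or fidelities")
        rows.append(flatten_field(r.field(quantity)))
    return OutputMatrix(values=np.vstack(rows), quantity=quantity, fidelity=fidelity, K=K, T=T)


def _gram_svd(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values and right singular vectors via the N x N Gram route."""
    G = Z @ Z.T
    evals, U = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, U = evals[order], U[:, order]
    evals = np.maximum(evals, 0.0)
    s = np.sqrt(evals)
    # the Gram route squares the condition number: singular values below
    # sqrt(eps) * s_max are numerical noise of the eigendecomposition
    cutoff = s[0] * np.sqrt(max(Z.shape) * np.finfo(float).eps)
    r = int(np.sum(s > cutoff))
    s, U = s[:r], U[:, :r]
    W = Z.T @ (U / s)
    # re-orthonormalize (Gram route loses digits on small singular values)
    W, R = np.linalg.qr(W)
    W *= np.sign(np.diag(R))
    return s, W


def fit_reduction(
    Z: OutputMatrix, threshold: float = 0.99, center: bool = False
) -> ReducedBasis:
    """Fit the truncated SVD basis of an output matrix.

    Uses the Gram-matrix route (N << M).  The variance ratio of component i
    is ``s_i^2 / sum s^2`` on the (by default uncentered) matrix.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if Z.N < 2:
        raise ValueError("need at least two rows to fit a reduction")
    values = Z.values
    mean = None
    if center:
        mean = values.mean(axis=0)
        values = values - mean
    if not np.any(values):
        raise ValueError("degenerate input: output matrix is identically zero")
    s, W = _gram_svd(values)
    # sign convention: largest-magnitude entry of each basis vector positive
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    W *= flip
    ratio = s**2 / np.sum(s**2)
    cum = np.cumsum(ratio)
    if threshold >= 1.0:
        k = s.size  # numerical rank
    else:
        k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return ReducedBasis(
        W=W,
        singular_values=s,
        k=k,
        threshold=threshold,
        quantity=Z.quantity,
        fidelity=Z.fidelity,
        K=Z.K,
        T=Z.T,
        centered=center,
        mean=mean,
    )


def transform(Z: OutputMatrix | np.ndarray, b: ReducedBasis) -> ScoreMatrix:
    """Project rows onto the truncated basis: ``Y_k = Z W_k``.

    Applies unchanged to out-of-sample rows, as required at surrogate
    inference time.
    """
    values = Z.values if isinstance(Z, OutputMatrix) else np.asarray(Z, dtype=float)
    if values.shape[-1] != b.W.shape[0]:
        raise ValueError("dimension mismatch between matrix and basis")
    if b.centered:
        values = values - b.mean
    return ScoreMatrix(scores=values @ b.W_k, basis=b)


def reconstruct(Y_k: ScoreMatrix | np.ndarray, b: ReducedBasis | None = None) -> OutputMatrix:
    """Inverse map ``Z_R = Y_k W_k^T`` back to flattened fields."""
    if isinstance(Y_k, ScoreMatrix):
        scores, b = Y_k.scores, Y_k.basis if b is None else b
    else:
        scores = np.asarray(Y_k, dtype=float)
        if b is None:
            raise ValueError("a basis is required to reconstruct raw scores")
    scores = np.atleast_2d(scores)
    if scores.shape[1] > b.W.shape[1]:
        raise ValueError("more score columns than basis components")
    values = scores @ b.W[:, : scores.shape[1]].T
    if b.centered:
        values = values + b.mean
    return OutputMatrix(values=values, quantity=b.quantity, fidelity=b.fidelity, K=b.K, T=b.T)
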