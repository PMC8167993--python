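"""Centered-kernel-alignment multiple kernel learning (MKL-CKA).

Given m training Gram matrices K_1..K_m and labels y in {+1, -1}^N, the
combined kernel is the convex combination K* = sum_i beta_i K_i with the
weights beta on the probability simplex.  Maximizing the centered kernel
alignment between K* and the ideal kernel y y^T is equivalent, after
squaring away the normalization, to the quadratic program

    min_beta  beta^T (M + lambda L) beta - 2 beta^T a
    s.t.      beta >= 0,  sum(beta) = 1

where

* a_i     = <U K_i U, y y^T>_F     (alignment of each centered kernel with
                                    the ideal kernel),
* M_{ef}  = <U K_e U, U K_f U>_F   (Gram matrix of the centered kernels
                                    under the Frobenius inner product),
* U       = I - (1/N) 1 1^T        (the centering matrix),
* L = D - W is the graph Laplacian of the kernel-kernel cosine-similarity
  matrix W_{ij} = <K_i, K_j>_F / (||K_i||_F ||K_j||_F); the penalty
  lambda * beta^T L beta = (lambda/2) * sum_{ij} W_ij (beta_i - beta_j)^2
  smooths the weights toward each other, preventing a single kernel from
  absorbing all the mass.

Both M and L are positive semidefinite, so the program is convex and its
minimizer on the simplex is unique whenever M + lambda*L is strictly
positive definite on the simplex's tangent space.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .kernels import KernelMatrix, KernelSet


def center_kernel(K: KernelMatrix | np.ndarray) -> KernelMatrix | np.ndarray:
    """Return U K U by row/column mean subtraction (U never materialized)."""
    if isinstance(K, KernelMatrix):
        if not K.is_square:
            raise ValueError("can only center a square kernel")
        return KernelMatrix(
            values=center_kernel(K.values),
            row_ids=list(K.row_ids),
            col_ids=list(K.col_ids),
            gamma=K.gamma,
            feature_name=K.feature_name,
        )
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {K.shape}")
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def alignment(P: np.ndarray, Q: np.ndarray) -> float:
    """Cosine similarity <P, Q>_F / (||P||_F ||Q||_F) between two matrices."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    np_, nq = np.linalg.norm(P), np.linalg.norm(Q)
    if np_ < 1e-300 or nq < 1e-300:
        raise ValueError("alignment undefined for a zero-norm matrix")
    return float(np.sum(P * Q) / (np_ * nq))


def centered_alignment(K: KernelMatrix | np.ndarray, y: np.ndarray) -> float:
    """Alignment between the centered kernel U K U and the ideal kernel y y^T."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    y = _check_labels(y, values.shape[0])
    Kc = center_kernel(values)
    norm_kc = np.linalg.norm(Kc)
    if norm_kc < 1e-300:
        raise ValueError("kernel centers to zero; centered alignment undefined")
    # <Kc, y y^T>_F = y^T Kc y, avoiding the N x N outer product.
    return float(y @ Kc @ y) / (norm_kc * len(y))  # ||y y^T||_F = N


def _check_labels(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != n:
        raise ValueError(f"label vector length {len(y)} != kernel size {n}")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    return y


@dataclasses.dataclass
class MKLProblem:
    """The quadratic-program data for one training kernel set."""

    a: np.ndarray        # m alignment inner products with the ideal kernel
    M: np.ndarray        # m x m Frobenius Gram matrix of centered kernels
    W: np.ndarray        # m x m kernel-kernel cosine similarities
    D: np.ndarray        # diagonal row sums of W
    L: np.ndarray        # graph Laplacian D - W
    lam: float           # smoothing strength lambda >= 0
    n_samples: int
    kernel_names: list[str] = dataclasses.field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.a)


@dataclasses.dataclass
class MKLSolution:
    beta: np.ndarray
    objective: float
    problem: MKLProblem

    def as_dict(self) -> dict[str, float]:
        names = self.problem.kernel_names or [
            f"K{i + 1}" for i in range(len(self.beta))
        ]
        return dict(zip(names, map(float, self.beta)))


def build_problem(
    kernels: KernelSet | list[np.ndarray],
    y: np.ndarray,
    lam: float = 0.8,
    centered_similarity: bool = False,
) -> MKLProblem:
    """Assemble a, M, W, D and L from square training kernels and labels.

    ``centered_similarity`` switches W to cosine similarity of the centered
    kernels; the default uses the raw kernels.
    """
    if isinstance(kernels, KernelSet):
        names = kernels.names
        mats = kernels.matrices()
        for k in kernels:
            if not k.is_square:
                raise ValueError("training kernels must be square")
    else:
        names = [f"K{i + 1}" for i in range(len(kernels))]
        mats = [np.asarray(K, dtype=float) for K in kernels]
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n = mats[0].shape[0]
    for K in mats:
        if K.shape != (n, n):
            raise ValueError("all kernels must be square with equal size")
    y = _check_labels(y, n)

    centered = [center_kernel(K) for K in mats]
    m = len(mats)
    a = np.array([y @ Kc @ y for Kc in centered])  # <U K U, y y^T>_F
    M = np.empty((m, m))
    for e in range(m):
        for f in range(e, m):
            M[e, f] = M[f, e] = np.sum(centered[e] * centered[f])
    sim_base = centered if centered_similarity else mats
    W = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            W[i, j] = W[j, i] = alignment(sim_base[i], sim_base[j])
    D = np.diag(W.sum(axis=1))
    L = D - W
    return MKLProblem(a=a, M=M, W=W, D=D, L=L, lam=lam, n_samples=n,
                      kernel_names=names)


def solve_weights(problem: MKLProblem) -> MKLSolution:
    """Solve min beta^T (M + lambda L) beta - 2 beta^T a on the simplex.

    Deterministic convex QP via SLSQP with the analytic gradient, started
    from the uniform weights.  Tiny negative components from floating-point
    (within 1e-9) are clipped and the weights renormalized; anything larger
    is a solver failure and raises.
    """
    m = problem.m
    Q = problem.M + problem.lam * problem.L
    Q = 0.5 * (Q + Q.T)
    # Both M (a Gram matrix) and L (a Laplacian) are PSD; guard regardless.
    min_eig = float(np.linalg.eigvalsh(Q).min())
    scale = max(float(np.abs(Q).max()), 1.0)
    if min_eig < -1e-8 * scale:
        raise ValueError(f"M + lambda*L is indefinite (min eigenvalue {min_eig:g})")
    a = problem.a

    def fun(b: np.ndarray) -> float:
        return float(b @ Q @ b - 2.0 * a @ b)

    def jac(b: np.ndarray) -> np.ndarray:
        return 2.0 * (Q @ b - a)

    # Condition the problem: SLSQP tolerances are absolute, so normalize by
    # the data magnitude (the minimizer is scale-invariant).
    norm = max(scale, float(np.abs(a).max()), 1.0)
    res = optimize.minimize(
        lambda b: fun(b) / norm,
        x0=np.full(m, 1.0 / m),
        jac=lambda b: jac(b) / norm,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0,
                      "jac": lambda b: np.ones_like(b)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"MKL weight solver failed: {res.message}")
    beta = res.x
    if beta.min() < -1e-9:
        raise RuntimeError(f"infeasible weights from solver: min {beta.min():g}")
    beta = np.clip(beta, 0.0, None)
    beta = beta / beta.sum()
    return MKLSolution(beta=beta, objective=fun(beta), problem=problem)


def mean_weights(m: int) -> np.ndarray:
    """Uniform weights 1/m — the mean-weighted-kernel baseline."""
    return np.full(m, 1.0 / m)


def combine_kernels(
    kernels: KernelSet | list[np.ndarray], beta: np.ndarray
) -> KernelMatrix | np.ndarray:
    """Elementwise convex combination K* = sum_i beta_i K_i.

    Works for square training sets and rectangular test-by-train sets alike.
    """
    beta = np.asarray(beta, dtype=float)
    n_k = len(kernels)
    if len(beta) != n_k:
        raise ValueError(f"{len(beta)} weights for {n_k} kernels")
    if np.any(beta < -1e-9) or abs(beta.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the probability simplex")
    if isinstance(kernels, KernelSet):
        values = sum(b * K.values for b, K in zip(beta, kernels))
        ref = kernels[0]
        return KernelMatrix(
            values=values,
            row_ids=list(ref.row_ids),
            col_ids=list(ref.col_ids),
            feature_name="combined",
        )
    return sum(b * np.asarray(K, dtype=float) for b, K in zip(beta, kernels))
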