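"""Network diffusion features: random walk with restart and SVD reduction.

Each node's diffusion state is the stationary distribution of a random
walk that restarts at that node with probability ``alpha``:

    p_{t+1} = (1 - alpha) * W p_t + alpha * p_0

where W = T^t is the column-action of the row-stochastic transition
matrix T (T_ij = G_ij / sum_k G_ik is the probability of stepping from
node i to node j).  Stacking the converged states row-wise gives the
diffusion-state matrix S, whose closed form is

    S = alpha * (I - (1 - alpha) T)^{-1}.

S is then factorized by SVD and each node is embedded as a row of
V_n * diag(sqrt(sigma_1..sigma_n)), the scaled top right-singular
directions, giving an n-dimensional topological signature per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .hetnet import HetNet


class ConvergenceError(RuntimeError):
    """RWR iteration failed to reach the requested tolerance."""


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix; isolated nodes get a self-loop."""

    T: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.T.shape[0]


@dataclass
class DiffusionStates:
    """Converged restart-walk distributions, one row per restart node."""

    alpha: float
    S: np.ndarray
    iterations_used: int
    residual: float


@dataclass
class EmbeddingFactorization:
    """Low-dimensional node embedding from the SVD of the diffusion states.

    ``X`` has one row per node and exactly ``n`` columns; if the
    diffusion matrix has fewer than ``n`` singular directions the extra
    columns are zero.
    """

    n: int
    singular_values: np.ndarray
    X: np.ndarray


def transition_matrix(net: HetNet) -> TransitionMatrix:
    """Row-normalize the global adjacency; isolated rows become self-loops."""
    G = net.G.tocsr().astype(float)
    degree = np.asarray(G.sum(axis=1)).ravel()
    isolated = degree == 0
    inv = np.zeros_like(degree)
    inv[~isolated] = 1.0 / degree[~isolated]
    T = sp.diags(inv) @ G
    if isolated.any():
        idx = np.flatnonzero(isolated)
        T = T.tolil()
        T[idx, idx] = 1.0
    return TransitionMatrix(T.tocsr())


def _walk_operator(T: TransitionMatrix) -> sp.csr_matrix:
    # probability flows i -> j with probability T_ij, so the column-vector
    # update applies T transposed
    return T.T.transpose().tocsr()


def rwr(
    T: TransitionMatrix,
    restart_index: int,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterate the restart walk from one node until the L1 change < tol."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = T.n_nodes
    if not 0 <= restart_index < n:
        raise IndexError(f"restart index {restart_index} out of range")
    if alpha == 1.0:
        p = np.zeros(n)
        p[restart_index] = 1.0
        return p
    W = _walk_operator(T)
    p0 = np.zeros(n)
    p0[restart_index] = 1.0
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (W @ p) + alpha * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return p
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def rwr_direct(T: TransitionMatrix, restart_index: int, alpha: float = 0.5) -> np.ndarray:
    """Exact fixed point alpha * (I - (1-alpha) W)^{-1} p0 by linear solve."""
    n = T.n_nodes
    W = _walk_operator(T).toarray()
    p0 = np.zeros(n)
    p0[restart_index] = 1.0
    return alpha * np.linalg.solve(np.eye(n) - (1.0 - alpha) * W, p0)


def diffusion_states(
    T: TransitionMatrix,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    solver: str = "iterative",
) -> DiffusionStates:
    """Compute every node's diffusion state (row i = restart at node i).

    ``solver='direct'`` performs one exact sparse LU solve, suitable up to
    a few thousand nodes; ``'iterative'`` applies the power iteration to
    all restart vectors simultaneously.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = T.n_nodes
    if solver == "direct":
        A = sp.eye(n, format="csc") - (1.0 - alpha) * T.T.transpose().tocsc()
        # A X = alpha * I; diffusion states are the columns of X
        X = scipy.linalg.solve(A.toarray(), alpha * np.eye(n))
        return DiffusionStates(alpha, X.T.copy(), iterations_used=0, residual=0.0)
    if solver != "iterative":
        raise ValueError(f"unknown solver {solver!r}")
    W = _walk_operator(T)
    P0 = np.eye(n)
    P = P0.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        P_next = (1.0 - alpha) * (W @ P) + alpha * P0
        residual = float(np.abs(P_next - P).sum(axis=0).max())
        P = P_next
        if residual < tol:
            return DiffusionStates(alpha, P.T.copy(), it, residual)
    raise ConvergenceError(
        f"diffusion states did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def svd_reduce(states: DiffusionStates, n: int = 500) -> EmbeddingFactorization:
    """Embed nodes as rows of V_n sqrt(Sigma_n) from the SVD of S.

    The sign of each right-singular vector is fixed so that its
    largest-magnitude entry is positive, making the embedding
    deterministic across runs.  When S has fewer than ``n`` singular
    directions the embedding is zero-padded to ``n`` columns.
    """
    if n < 1:
        raise ValueError("embedding dimension must be >= 1")
    S = states.S
    n_nodes = S.shape[0]
    U, sigma, Vt = scipy.linalg.svd(S, full_matrices=False)
    k = min(n, len(sigma))
    Vt_k = Vt[:k].copy()
    for r in range(k):
        j = int(np.argmax(np.abs(Vt_k[r])))
        if Vt_k[r, j] < 0:
            Vt_k[r] *= -1.0
    X = Vt_k.T * np.sqrt(sigma[:k])
    if k < n:
        warnings.warn(
            f"diffusion matrix has only {k} singular directions; "
            f"padding embedding to {n} columns with zeros",
            stacklevel=2,
        )
        X = np.hstack([X, np.zeros((n_nodes, n - k))])
    return EmbeddingFactorization(n=n, singular_values=sigma[:k].copy(), X=X)
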