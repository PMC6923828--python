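"""Linear neighborhood similarity (LNS) learning.

Each entity (a lncRNA or miRNA described by a nonnegative feature vector,
e.g. k-mer frequencies or an interaction profile) is reconstructed as a
nonnegative, sum-to-one weighted combination of its nearest neighbors in
Euclidean distance.  The learned weight matrix W doubles as a directed
similarity graph: W[i, j] is how much neighbor j contributes to
reconstructing entity i.

The optimization problem is

    min_W  1/2 ||X - (C .* W) X||_F^2  +  mu/2 * sum_i [((C .* W) e)_i]^2
    s.t.   (C .* W) e = e,  W >= 0

where C is the binary neighbor-indicator matrix and e the all-ones vector.
The problem separates over rows: row i is a quadratic program over the
probability simplex on its neighbor set.  Two facts shape the solver:

* On the constraint set (row sums exactly 1) the mu-penalty is the
  constant mu*n/2, so the constrained optimum does not depend on mu.
* With sum(w) = 1 the residual x_i - sum_j w_j x_j is unchanged by
  translating all features by a common vector, so the feature matrix can
  be centered first.  Centering is essential numerically: k-mer
  frequency vectors (and interaction profiles of similar entities)
  cluster tightly around a common offset, and the offset would otherwise
  dominate the curvature and stall any first-order scheme.

Each iteration takes a gradient step of length 1/L on the centered
reconstruction objective (L = largest eigenvalue of the centered Gram
matrix) and projects every row back onto the simplex over its neighbor
support.  With the exact 1/L step the objective is non-increasing, every
iterate is row-stochastic and supported on C, and the fixed point is the
exact KKT point of the row quadratic program.  A multiplier-free
multiplicative update is a popular alternative for this problem but only
approximates the sum-to-one constraint (it treats the constraint's
Lagrange multiplier as the constant mu, which is justified when every
point is exactly reconstructible by its neighbors); the projected scheme
needs no such assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import InteractionMatrix
from .sequence_features import FeatureMatrix

_DENOM_FLOOR = 1e-12  # floor for norms/eigenvalues used as divisors


@dataclass
class LNSConfig:
    """Parameters of the linear neighborhood similarity solve.

    neighbor_ratio
        Fraction K of the other n-1 entities selected as nearest
        neighbors; the neighbor count is max(1, floor(K * (n - 1))).
    mu
        Tradeoff between reconstruction error and the squared row-sum
        penalty.  Because the solver enforces the row-sum constraint
        exactly, mu shifts the objective by a constant and does not
        change the learned similarities; it is kept so reported
        objective values are comparable across configurations.
    max_iter, tol
        The solve stops when the relative Frobenius change of W drops
        below ``tol`` or after ``max_iter`` projected-gradient steps.
    """

    neighbor_ratio: float = 0.8
    mu: float = 1.0
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.neighbor_ratio <= 1.0:
            raise ValueError(f"neighbor_ratio must be in (0, 1], got {self.neighbor_ratio}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass
class NeighborIndicator:
    """Binary matrix C with C[i, j] = 1 iff j is a selected neighbor of i."""

    C: np.ndarray
    neighbor_ratio: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if np.any(np.diag(self.C) != 0):
            raise ValueError("self-neighbors are not allowed (diagonal must be 0)")


@dataclass
class SimilarityMatrix:
    """Square nonnegative similarity matrix with aligned entity ids.

    LNS output rows lie on the probability simplex over the selected
    neighbors; rows of entities excluded from the solve (no interaction
    profile) are all-zero.
    """

    W: np.ndarray
    entity_ids: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.entity_ids)
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} ids")
        if np.any(self.W < 0):
            raise ValueError("similarity matrix must be nonnegative")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.X, dtype=float)
    return np.asarray(X, dtype=float)


def _entity_ids(X, n: int) -> list[str]:
    if isinstance(X, FeatureMatrix):
        return list(X.entity_ids)
    return [str(i) for i in range(n)]


def n_neighbors(n_entities: int, neighbor_ratio: float) -> int:
    """Neighbor count for n entities: max(1, floor(K * (n - 1)))."""
    return max(1, int(np.floor(neighbor_ratio * (n_entities - 1))))


def select_neighbors(X, neighbor_ratio: float) -> NeighborIndicator:
    """Mark, per row, the nearest neighbors in Euclidean distance.

    Self is excluded; distance ties are broken by ascending entity index
    so the selection is deterministic.
    """
    A = _as_array(X)
    n = A.shape[0]
    if n < 2:
        raise ValueError("neighbor selection needs at least 2 entities")
    k = n_neighbors(n, neighbor_ratio)
    D = cdist(A, A)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")  # stable => ties by index
    C = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    C[rows, order[:, :k].ravel()] = 1.0
    return NeighborIndicator(C, neighbor_ratio)


def lns_objective(X, W: np.ndarray, C: np.ndarray, mu: float) -> float:
    """Value of the constrained reconstruction objective at W."""
    A = _as_array(X)
    Wm = W.W if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    Cm = C.C if isinstance(C, NeighborIndicator) else np.asarray(C, dtype=float)
    if Wm.shape != Cm.shape or Wm.shape[0] != A.shape[0]:
        raise ValueError("shape mismatch between X, W and C")
    M = Cm * Wm
    recon = 0.5 * np.linalg.norm(A - M @ A, "fro") ** 2
    penalty = 0.5 * mu * float(np.sum(M.sum(axis=1) ** 2))
    return float(recon + penalty)


def _project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    j = np.arange(1, V.shape[1] + 1)
    rho = np.count_nonzero(U * j > css, axis=1)
    theta = css[np.arange(V.shape[0]), rho - 1] / rho
    return np.maximum(V - theta[:, None], 0.0)


def lns_similarity(
    X,
    cfg: LNSConfig | None = None,
    objective_trace: list[float] | None = None,
) -> SimilarityMatrix:
    """Learn the linear neighborhood similarity matrix from features.

    W starts uniform over each entity's neighbor set; each sweep takes a
    1/L gradient step on the centered reconstruction objective and
    projects every row back onto the probability simplex over its
    neighbor support, so every iterate (and the result) is exactly
    row-stochastic, nonnegative and supported on C.  Stops when the
    relative Frobenius change falls below ``cfg.tol``.

    If ``objective_trace`` is a list, the value of :func:`lns_objective`
    at the initial point and after every sweep is appended to it.
    """
    cfg = cfg or LNSConfig()
    A = _as_array(X)
    if not np.isfinite(A).all():
        raise ValueError("feature matrix contains non-finite values")
    n = A.shape[0]
    if n < 2:
        raise ValueError("LNS needs at least 2 entities")
    nbr = select_neighbors(A, cfg.neighbor_ratio)
    k = n_neighbors(n, cfg.neighbor_ratio)
    idx = np.argsort(-nbr.C, axis=1, kind="stable")[:, :k]
    idx.sort(axis=1)  # (n, k) neighbor indices per row

    Ac = A - A.mean(axis=0)  # translation-invariant under the simplex constraint
    G = Ac @ Ac.T
    L = max(float(np.linalg.eigvalsh(G)[-1]), _DENOM_FLOOR)
    step = 1.0 / L

    rows = np.arange(n)[:, None]
    Wk = np.full((n, k), 1.0 / k)  # compact (n, k) weights over each support
    W = np.zeros((n, n))
    W[rows, idx] = Wk
    if objective_trace is not None:
        objective_trace.append(lns_objective(A, W, nbr.C, cfg.mu))
    for _ in range(cfg.max_iter):
        grad = (W @ G - G)[rows, idx]
        Wk_new = _project_rows_to_simplex(Wk - step * grad)
        delta = np.linalg.norm(Wk_new - Wk)
        scale = max(np.linalg.norm(Wk), _DENOM_FLOOR)
        Wk = Wk_new
        W = np.zeros((n, n))
        W[rows, idx] = Wk
        if objective_trace is not None:
            objective_trace.append(lns_objective(A, W, nbr.C, cfg.mu))
        if delta / scale < cfg.tol:
            break
    return SimilarityMatrix(W, _entity_ids(X, n))


def interaction_profile_similarity(
    Y: InteractionMatrix, side: str, cfg: LNSConfig | None = None
) -> SimilarityMatrix:
    """LNS over interaction profiles (rows of Y for lncRNAs, columns for miRNAs).

    Entities with an all-zero profile have no usable interaction
    information: they are excluded from the solve, and both their row and
    column in the returned matrix are all zeros.
    """
    if side == "lncRNA":
        profiles, ids = Y.Y, Y.lnc_ids
    elif side == "miRNA":
        profiles, ids = Y.Y.T, Y.mir_ids
    else:
        raise ValueError(f"side must be 'lncRNA' or 'miRNA', got {side!r}")
    active = profiles.sum(axis=1) > 0
    n_active = int(active.sum())
    if n_active < 2:
        raise ValueError(
            f"interaction profile similarity needs >= 2 {side}s with interactions, "
            f"found {n_active}"
        )
    sub = lns_similarity(profiles[active], cfg).W
    n = profiles.shape[0]
    W = np.zeros((n, n))
    idx = np.flatnonzero(active)
    W[np.ix_(idx, idx)] = sub
    return SimilarityMatrix(W, list(ids))
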