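"""Label propagation scoring and the two SLNPM pipelines.

Scores for every lncRNA-miRNA pair come from diffusing the known
interaction labels over two directed similarity graphs.  On the lncRNA
graph each miRNA's interaction column is the initial label vector; on the
miRNA graph each lncRNA's row plays that role.  The recurrence

    F <- alpha * S @ F + (1 - alpha) * Y0

with row-stochastic S and absorbing probability alpha in (0, 1) converges
to the fixed point (1 - alpha) * (I - alpha S)^{-1} Y0.  The two graph
scores are fused as P = beta * P_lnc + (1 - beta) * P_mir.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import InteractionMatrix
from .integration import complement_profiles_pc, integrate_sc, pc_similarities
from .lns import (
    LNSConfig,
    SimilarityMatrix,
    interaction_profile_similarity,
    lns_similarity,
)
from .sequence_features import FeatureMatrix

_ROW_SUM_TOL = 1e-6

# parameter choices used throughout: SC learns similarities over 80% of
# available neighbors, PC over 90%; both propagate with alpha=0.4 and fuse
# with beta=0.25 (the miRNA graph carries most of the weight)
SC_LNS_DEFAULTS = dict(neighbor_ratio=0.8)
PC_LNS_DEFAULTS = dict(neighbor_ratio=0.9)


@dataclass
class PropagationConfig:
    """Label propagation parameters.

    alpha
        Absorbing probability in (0, 1): the fraction of label mass that
        keeps diffusing each step (the rest is re-injected from Y0).
    beta
        Weight of the lncRNA-graph prediction in the final fusion;
        1 - beta goes to the miRNA-graph prediction.
    """

    alpha: float = 0.4
    beta: float = 0.25
    max_iter: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass
class PredictionMatrix:
    """Real-valued lncRNA x miRNA score matrix with aligned id lists."""

    P: np.ndarray
    lnc_ids: list[str]
    mir_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.lnc_ids), len(self.mir_ids)):
            raise ValueError("P shape does not match id lists")
        if not np.isfinite(self.P).all():
            raise ValueError("prediction matrix contains non-finite values")


def _similarity_array(S) -> np.ndarray:
    return S.W if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)


def _check_rows(S: np.ndarray) -> None:
    sums = S.sum(axis=1)
    # all-zero rows (entities excluded from a similarity solve) are
    # permitted: they simply retain their injected labels
    bad = ~(np.isclose(sums, 1.0, atol=_ROW_SUM_TOL) | (sums == 0.0))
    if bad.any():
        raise ValueError(
            f"similarity matrix is not row-stochastic: rows {np.flatnonzero(bad)[:5]} "
            f"sum to {sums[bad][:5]}"
        )


def label_propagate(
    S,
    Y0: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterate F <- alpha S F + (1 - alpha) Y0 from F = Y0 to convergence.

    Stops when the max-abs change between sweeps drops below ``tol``;
    warns (and returns the current iterate) if ``max_iter`` is hit first.
    """
    A = _similarity_array(S)
    Y0 = np.asarray(Y0, dtype=float)
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if Y0.shape[0] != A.shape[0]:
        raise ValueError("Y0 must have one row per similarity-graph node")
    _check_rows(A)
    if alpha == 0.0:
        return Y0.copy()
    F = Y0.copy()
    for _ in range(max_iter):
        F_next = alpha * (A @ F) + (1.0 - alpha) * Y0
        if np.max(np.abs(F_next - F)) < tol:
            return F_next
        F = F_next
    warnings.warn(
        f"label propagation did not converge in {max_iter} iterations", stacklevel=2
    )
    return F


def label_propagate_closed_form(S, Y0: np.ndarray, alpha: float) -> np.ndarray:
    """Exact fixed point (1 - alpha) (I - alpha S)^{-1} Y0.

    Independent direct-solve route; exists because the spectral radius of
    alpha*S is at most alpha < 1 for (sub)stochastic S.
    """
    A = _similarity_array(S)
    Y0 = np.asarray(Y0, dtype=float)
    n = A.shape[0]
    return (1.0 - alpha) * np.linalg.solve(np.eye(n) - alpha * A, Y0)


def predict(
    Y_train: InteractionMatrix,
    S_L: SimilarityMatrix,
    S_M: SimilarityMatrix,
    cfg: PropagationConfig | None = None,
) -> PredictionMatrix:
    """Propagate on both similarity graphs and fuse with the beta weight.

    P_lnc propagates each miRNA's interaction column over the lncRNA
    graph; P_mir propagates each lncRNA's row over the miRNA graph.
    """
    cfg = cfg or PropagationConfig()
    l, m = Y_train.shape
    if _similarity_array(S_L).shape != (l, l) or _similarity_array(S_M).shape != (m, m):
        raise ValueError("similarity matrices not aligned with Y_train")
    P_lnc = label_propagate(S_L, Y_train.Y, cfg.alpha, cfg.tol, cfg.max_iter)
    P_mir = label_propagate(S_M, Y_train.Y.T, cfg.alpha, cfg.tol, cfg.max_iter).T
    P = cfg.beta * P_lnc + (1.0 - cfg.beta) * P_mir
    return PredictionMatrix(P, list(Y_train.lnc_ids), list(Y_train.mir_ids))


def _sequence_similarities(
    X_lnc: FeatureMatrix,
    X_mir: FeatureMatrix,
    lns_cfg: LNSConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    return lns_similarity(X_lnc, lns_cfg), lns_similarity(X_mir, lns_cfg)


def slnpm_sc(
    Y_train: InteractionMatrix,
    X_lnc: FeatureMatrix,
    X_mir: FeatureMatrix,
    lns_cfg: LNSConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    S_LSF: SimilarityMatrix | None = None,
    S_MSF: SimilarityMatrix | None = None,
) -> PredictionMatrix:
    """Similarity-combination pipeline (SLNPM-SC).

    Sequence similarities and interaction-profile similarities are
    learned separately, merged by the row-level SC switch, and propagated.
    Precomputed sequence similarities may be passed in (they do not
    depend on the training interactions, so cross-validation reuses them).
    """
    lns_cfg = lns_cfg or LNSConfig(**SC_LNS_DEFAULTS)
    prop_cfg = prop_cfg or PropagationConfig()
    if S_LSF is None:
        S_LSF = lns_similarity(X_lnc, lns_cfg)
    if S_MSF is None:
        S_MSF = lns_similarity(X_mir, lns_cfg)
    S_LIP = interaction_profile_similarity(Y_train, "lncRNA", lns_cfg)
    S_MIP = interaction_profile_similarity(Y_train, "miRNA", lns_cfg)
    S_LIS = integrate_sc(S_LIP, S_LSF, Y_train, "lncRNA")
    S_MIS = integrate_sc(S_MIP, S_MSF, Y_train, "miRNA")
    return predict(Y_train, S_LIS, S_MIS, prop_cfg)


def slnpm_pc(
    Y_train: InteractionMatrix,
    X_lnc: FeatureMatrix,
    X_mir: FeatureMatrix,
    lns_cfg: LNSConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    k_nn: int = 10,
    S_LSF: SimilarityMatrix | None = None,
    S_MSF: SimilarityMatrix | None = None,
) -> PredictionMatrix:
    """Profile-complementation pipeline (SLNPM-PC).

    Missing interaction profiles are imputed from sequence neighbors,
    profile similarity is learned on the completed matrix, and the scores
    are propagated as in SC.
    """
    lns_cfg = lns_cfg or LNSConfig(**PC_LNS_DEFAULTS)
    prop_cfg = prop_cfg or PropagationConfig()
    if S_LSF is None:
        S_LSF = lns_similarity(X_lnc, lns_cfg)
    if S_MSF is None:
        S_MSF = lns_similarity(X_mir, lns_cfg)
    Yc = complement_profiles_pc(Y_train, S_LSF, S_MSF, k_nn)
    S_L, S_M = pc_similarities(Yc, lns_cfg, Y_train.lnc_ids, Y_train.mir_ids)
    return predict(Y_train, S_L, S_M, prop_cfg)


def profile_only(
    Y_train: InteractionMatrix,
    lns_cfg: LNSConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
) -> PredictionMatrix:
    """Baseline using interaction-profile similarity alone.

    Cold-start entities keep all-zero similarity rows, so their scores
    stay at zero: this model cannot rank pairs involving them.
    """
    lns_cfg = lns_cfg or LNSConfig(**SC_LNS_DEFAULTS)
    S_LIP = interaction_profile_similarity(Y_train, "lncRNA", lns_cfg)
    S_MIP = interaction_profile_similarity(Y_train, "miRNA", lns_cfg)
    return predict(Y_train, S_LIP, S_MIP, prop_cfg)


def sequence_only(
    Y_train: InteractionMatrix,
    X_lnc: FeatureMatrix,
    X_mir: FeatureMatrix,
    lns_cfg: LNSConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    S_LSF: SimilarityMatrix | None = None,
    S_MSF: SimilarityMatrix | None = None,
) -> PredictionMatrix:
    """Baseline using k-mer sequence similarity alone."""
    lns_cfg = lns_cfg or LNSConfig(**SC_LNS_DEFAULTS)
    if S_LSF is None:
        S_LSF = lns_similarity(X_lnc, lns_cfg)
    if S_MSF is None:
        S_MSF = lns_similarity(X_mir, lns_cfg)
    return predict(Y_train, S_LSF, S_MSF, prop_cfg)
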