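"""Cold-start information combination strategies.

A cold-start entity is a lncRNA or miRNA with no known interaction; its
interaction profile is all-zero, so profile-based similarity carries no
information about it.  Two strategies make such entities predictable:

SC (similarity combination)
    Row-level switch between similarity matrices: entities with at least
    one known interaction keep their interaction-profile similarity row,
    cold entities get their sequence-similarity row instead.

PC (profile complementation)
    The missing interaction profile itself is imputed as a
    similarity-weighted average of the profiles of the most
    sequence-similar entities that do have interactions; profile
    similarity is then learned from the completed matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_io import InteractionMatrix
from .lns import LNSConfig, SimilarityMatrix, lns_similarity


def integrate_sc(
    S_IP: SimilarityMatrix,
    S_SF: SimilarityMatrix,
    Y: InteractionMatrix,
    side: str,
) -> SimilarityMatrix:
    """Row-wise switch: profile-similarity row if the entity has any known
    interaction, sequence-similarity row otherwise.  Nothing is blended."""
    if side == "lncRNA":
        has_interactions = Y.Y.sum(axis=1) > 0
        ids = Y.lnc_ids
    elif side == "miRNA":
        has_interactions = Y.Y.sum(axis=0) > 0
        ids = Y.mir_ids
    else:
        raise ValueError(f"side must be 'lncRNA' or 'miRNA', got {side!r}")
    n = len(ids)
    for name, S in (("S_IP", S_IP), ("S_SF", S_SF)):
        if S.W.shape != (n, n):
            raise ValueError(f"{name} shape {S.W.shape} does not match {n} {side}s")
        if S.entity_ids != list(ids):
            raise ValueError(f"{name} entity order does not match Y")
    W = np.where(has_interactions[:, None], S_IP.W, S_SF.W)
    return SimilarityMatrix(W, list(ids))


def _complement_rows(
    M: np.ndarray,
    binary_profiles: np.ndarray,
    S: np.ndarray,
    k_nn: int,
    label: str,
) -> None:
    """Impute all-zero rows of M in place from similar interacting rows."""
    has_inter = binary_profiles.sum(axis=1) > 0
    eligible = np.flatnonzero(has_inter)
    for i in np.flatnonzero(~has_inter):
        sims = S[i, eligible]
        # top k_nn by similarity, ties broken by ascending entity index
        order = np.lexsort((eligible, -sims))[:k_nn]
        chosen = eligible[order]
        weights = S[i, chosen]
        Q = weights.sum()
        if Q <= 0:
            warnings.warn(
                f"{label} {i} has zero similarity to all eligible neighbors; "
                "using their unweighted mean profile",
                stacklevel=3,
            )
            weights = np.ones(len(chosen))
            Q = float(len(chosen))
        M[i] = weights @ M[chosen] / Q


def complement_profiles_pc(
    Y,
    S_LSF: SimilarityMatrix,
    S_MSF: SimilarityMatrix,
    k_nn: int = 10,
) -> np.ndarray:
    """Fill in all-zero interaction profiles from sequence neighbors.

    Each cold lncRNA row (then each cold miRNA column) becomes the
    normalized similarity-weighted average of the profiles of its
    ``k_nn`` most sequence-similar counterparts having at least one known
    interaction.  Rows/columns that already contain interactions are
    returned unchanged; imputed entries are convex combinations of
    existing profiles and therefore lie in [0, 1].  ``Y`` may be a binary
    :class:`~slnpm.data_io.InteractionMatrix` or an already-complemented
    real matrix, making the operation idempotent.
    """
    if k_nn < 1:
        raise ValueError(f"k_nn must be >= 1, got {k_nn}")
    Yb = Y.Y if isinstance(Y, InteractionMatrix) else np.asarray(Y, dtype=float)
    if Yb.sum() == 0:
        raise ValueError("cannot complement profiles: no known interactions at all")
    M = Yb.astype(float).copy()
    _complement_rows(M, Yb, S_LSF.W, k_nn, "lncRNA")
    # miRNA side works on columns; neighbor eligibility uses the original
    # binary profiles, values come from the row-completed matrix
    Mt = M.T.copy()
    _complement_rows(Mt, Yb.T, S_MSF.W, k_nn, "miRNA")
    return Mt.T


def pc_similarities(
    Y_complemented: np.ndarray,
    cfg: LNSConfig | None = None,
    lnc_ids: list[str] | None = None,
    mir_ids: list[str] | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """LNS similarity over rows (lncRNAs) and columns (miRNAs) of the
    complemented interaction matrix.

    Raises if any profile is still all-zero (possible when a cold entity
    had no interacting neighbor at all); a larger ``k_nn`` in the
    complementation step is the remedy.
    """
    M = np.asarray(Y_complemented, dtype=float)
    l, m = M.shape
    if np.any(M.sum(axis=1) == 0) or np.any(M.sum(axis=0) == 0):
        raise ValueError(
            "complemented interaction matrix still has an all-zero profile; "
            "increase k_nn so every cold entity reaches an interacting neighbor"
        )
    lnc_ids = lnc_ids if lnc_ids is not None else [str(i) for i in range(l)]
    mir_ids = mir_ids if mir_ids is not None else [str(j) for j in range(m)]
    S_L = lns_similarity(M, cfg)
    S_M = lns_similarity(M.T, cfg)
    return (
        SimilarityMatrix(S_L.W, list(lnc_ids)),
        SimilarityMatrix(S_M.W, list(mir_ids)),
    )
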