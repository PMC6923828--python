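"""Cross-validated evaluation of interaction predictors.

Protocol: the known interactions (positives) are randomly split into
n_folds subsets; in each fold the held-out positives are masked to 0 in
the training matrix, the entire pipeline (similarities, complementation)
is rebuilt on the masked matrix, and all pairs except the remaining
training positives are scored.  Held-out positives count as label 1,
never-observed pairs as label 0 (the full unobserved complement serves as
the negative set — no negative sampling).  Metrics are computed per fold
and averaged over n_runs independent repetitions.

AUC is the probability that a random positive outscores a random negative
(ties counting one half); AUPR is non-interpolated average precision.
The thresholded metrics (REC, SP, PR, ACC, F1) use a rank cutoff by
default: the top-r ranked pairs are called positive, where r is the
number of true positives in the evaluated set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import InteractionMatrix
from .lns import LNSConfig, lns_similarity
from .propagation import (
    PC_LNS_DEFAULTS,
    SC_LNS_DEFAULTS,
    PredictionMatrix,
    PropagationConfig,
    profile_only,
    sequence_only,
    slnpm_pc,
    slnpm_sc,
)
from .sequence_features import FeatureMatrix

METRIC_NAMES = ("aupr", "auc", "rec", "sp", "pr", "acc", "f1")


@dataclass
class MetricSet:
    """One evaluation's metric values, all in [0, 1]."""

    aupr: float
    auc: float
    rec: float
    sp: float
    pr: float
    acc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class CVConfig:
    n_folds: int = 5
    n_runs: int = 20
    seed: int = 0
    threshold_rule: str = "rank"  # "rank" or a fixed numeric cutoff via `threshold`
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.threshold_rule not in ("rank", "fixed"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_rule == "fixed" and self.threshold is None:
            raise ValueError("fixed threshold rule needs a threshold value")


def split_folds(
    Y: InteractionMatrix, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Partition the positive (i, j) pairs into n_folds near-equal subsets.

    Fold sizes differ by at most one; the partition is deterministic for
    a given seed.
    """
    positives = np.argwhere(Y.Y == 1.0)
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive pairs, found {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(positives), n_folds)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative label")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Non-interpolated average precision (area under the PR curve).

    Tied scores are treated as a single threshold group, so any strictly
    monotone transform of the scores leaves the value unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a threshold group ends (last occurrence of each score)
    boundaries = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    ends = np.append(boundaries, len(s) - 1)
    tp = np.cumsum(y)[ends]
    n_at = ends + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    recall_prev = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - recall_prev) * precision))


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold_rule: str = "rank",
    threshold: float | None = None,
) -> MetricSet:
    """Threshold-free (AUC, AUPR) and thresholded metrics for one score vector.

    With the default ``rank`` rule the top-r pairs are called positive,
    r being the number of true positives; with ``fixed``, pairs scoring
    strictly above ``threshold`` are called positive.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    auc = auc_score(scores, labels)
    aupr = average_precision(scores, labels)

    n = len(labels)
    n_pos = int(labels.sum())
    if threshold_rule == "rank":
        order = np.lexsort((np.arange(n), -scores))  # ties: ascending index
        predicted = np.zeros(n, dtype=bool)
        predicted[order[:n_pos]] = True
    elif threshold_rule == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold rule needs a threshold value")
        predicted = scores > threshold
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")

    pos = labels == 1
    tp = int(np.sum(predicted & pos))
    fp = int(np.sum(predicted & ~pos))
    fn = int(np.sum(~predicted & pos))
    tn = n - tp - fp - fn
    rec = tp / n_pos
    sp = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    pr = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    acc = (tp + tn) / n
    f1 = 2 * pr * rec / (pr + rec) if (pr + rec) > 0 else 0.0
    return MetricSet(aupr=aupr, auc=auc, rec=rec, sp=sp, pr=pr, acc=acc, f1=f1)


def _run_pipeline(
    method: str,
    Y_train: InteractionMatrix,
    X_lnc: FeatureMatrix | None,
    X_mir: FeatureMatrix | None,
    lns_cfg: LNSConfig | None,
    prop_cfg: PropagationConfig | None,
    k_nn: int,
    S_LSF,
    S_MSF,
) -> PredictionMatrix:
    if method == "sc":
        return slnpm_sc(Y_train, X_lnc, X_mir, lns_cfg, prop_cfg, S_LSF, S_MSF)
    if method == "pc":
        return slnpm_pc(Y_train, X_lnc, X_mir, lns_cfg, prop_cfg, k_nn, S_LSF, S_MSF)
    if method == "profile":
        return profile_only(Y_train, lns_cfg, prop_cfg)
    if method == "sequence":
        return sequence_only(Y_train, X_lnc, X_mir, lns_cfg, prop_cfg, S_LSF, S_MSF)
    raise ValueError(f"unknown method {method!r}")


def evaluate_fold(
    P: PredictionMatrix,
    Y_full: InteractionMatrix,
    Y_train: InteractionMatrix,
    cv_cfg: CVConfig | None = None,
) -> MetricSet:
    """Score one fold: all pairs except training positives, held-out
    positives labelled 1, never-observed pairs labelled 0."""
    cv_cfg = cv_cfg or CVConfig()
    eval_mask = Y_train.Y == 0.0
    scores = P.P[eval_mask]
    labels = Y_full.Y[eval_mask]
    return compute_metrics(scores, labels, cv_cfg.threshold_rule, cv_cfg.threshold)


def cross_validate(
    Y: InteractionMatrix,
    X_lnc: FeatureMatrix | None = None,
    X_mir: FeatureMatrix | None = None,
    method: str = "sc",
    lns_cfg: LNSConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    cv_cfg: CVConfig | None = None,
    k_nn: int = 10,
) -> tuple[pd.DataFrame, MetricSet]:
    """Repeated k-fold cross-validation of one pipeline.

    Returns the per-fold metric table (one row per run x fold) and the
    arithmetic mean over all folds of all runs.  Run r uses seed
    ``cv_cfg.seed + r`` so runs are independent yet reproducible.
    Sequence similarities do not depend on the training interactions and
    are computed once and shared across folds.
    """
    cv_cfg = cv_cfg or CVConfig()
    if method in ("sc", "pc", "sequence") and (X_lnc is None or X_mir is None):
        raise ValueError(f"method {method!r} requires sequence feature matrices")
    if lns_cfg is None and method in ("sc", "pc"):
        defaults = SC_LNS_DEFAULTS if method == "sc" else PC_LNS_DEFAULTS
        lns_cfg = LNSConfig(**defaults)

    S_LSF = S_MSF = None
    if method in ("sc", "pc", "sequence"):
        S_LSF = lns_similarity(X_lnc, lns_cfg)
        S_MSF = lns_similarity(X_mir, lns_cfg)

    records = []
    for run in range(cv_cfg.n_runs):
        folds = split_folds(Y, cv_cfg.n_folds, cv_cfg.seed + run)
        for fold_idx, fold in enumerate(folds):
            Y_train = Y.copy()
            Y_train.Y[fold[:, 0], fold[:, 1]] = 0.0
            P = _run_pipeline(
                method, Y_train, X_lnc, X_mir, lns_cfg, prop_cfg, k_nn, S_LSF, S_MSF
            )
            metrics = evaluate_fold(P, Y, Y_train, cv_cfg)
            records.append({"run": run, "fold": fold_idx, **metrics.as_dict()})
    table = pd.DataFrame.from_records(records)
    means = MetricSet(**{name: float(table[name].mean()) for name in METRIC_NAMES})
    return table, means


def topk_recall(
    P: PredictionMatrix,
    held_out: Iterable[tuple[int, int]],
    train_pos: Iterable[tuple[int, int]],
    ks: Sequence[int],
) -> dict[int, int]:
    """How many held-out positives appear among the top-k ranked pairs.

    Training positives are excluded from the ranking; ties are broken by
    (lncRNA id, miRNA id) so counts are deterministic.
    """
    ks = list(ks)
    if any(k2 < k1 for k1, k2 in zip(ks, ks[1:])):
        raise ValueError("ks must be ascending")
    train_set = {tuple(p) for p in train_pos}
    held_set = {tuple(p) for p in held_out}
    candidates = [
        (-P.P[i, j], P.lnc_ids[i], P.mir_ids[j], (i, j))
        for i in range(len(P.lnc_ids))
        for j in range(len(P.mir_ids))
        if (i, j) not in train_set
    ]
    if ks and ks[-1] > len(candidates):
        raise ValueError(f"k={ks[-1]} exceeds the {len(candidates)} candidate pairs")
    candidates.sort()
    hits = np.cumsum([c[3] in held_set for c in candidates])
    return {k: int(hits[k - 1]) if k > 0 else 0 for k in ks}


def grid_search(
    Y: InteractionMatrix,
    X_lnc: FeatureMatrix | None,
    X_mir: FeatureMatrix | None,
    method: str,
    k_grid: Sequence[float],
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    cv_cfg: CVConfig | None = None,
    mu: float = 1.0,
    k_nn: int = 10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full-factorial parameter search maximizing mean AUPR.

    Returns the per-combination table and the AUPR-maximizing
    (neighbor_ratio, alpha, beta) triple.  A reduced ``cv_cfg.n_runs``
    keeps large grids tractable.
    """
    if not (len(k_grid) and len(alpha_grid) and len(beta_grid)):
        raise ValueError("all three parameter grids must be nonempty")
    cv_cfg = cv_cfg or CVConfig(n_runs=1)
    rows = []
    for K, alpha, beta in itertools.product(k_grid, alpha_grid, beta_grid):
        lns_cfg = LNSConfig(neighbor_ratio=K, mu=mu)
        prop_cfg = PropagationConfig(alpha=alpha, beta=beta)
        _, means = cross_validate(
            Y, X_lnc, X_mir, method, lns_cfg, prop_cfg, cv_cfg, k_nn
        )
        rows.append(
            {"neighbor_ratio": K, "alpha": alpha, "beta": beta, **means.as_dict()}
        )
    table = pd.DataFrame.from_records(rows)
    best = table.loc[table["aupr"].idxmax()]
    return table, {
        "neighbor_ratio": float(best["neighbor_ratio"]),
        "alpha": float(best["alpha"]),
        "beta": float(best["beta"]),
        "aupr": float(best["aupr"]),
    }
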