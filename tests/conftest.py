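"""Shared fixtures: small simulated datasets and independent oracles."""

import itertools

import numpy as np
import pytest

from slnpm import SimulationConfig, kmer_features, simulate


def simplex_qp_oracle(G: np.ndarray, mu: float) -> np.ndarray:
    """Exact minimizer of 1/2 w'Gw + mu/2 (sum w)^2 over the simplex.

    Independent of the package's solver: enumerates every active set and
    solves the equality-constrained KKT system directly.  Exponential in
    the number of variables, so only usable for small neighborhoods.
    """
    m = G.shape[0]
    H = G + mu  # on the simplex the mu-term is mu/2 * (w'ee'w)
    best, best_obj = None, np.inf
    for r in range(1, m + 1):
        for S in itertools.combinations(range(m), r):
            S = list(S)
            A = np.zeros((r + 1, r + 1))
            A[:r, :r] = H[np.ix_(S, S)]
            A[:r, r] = -1.0
            A[r, :r] = 1.0
            b = np.zeros(r + 1)
            b[r] = 1.0
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            w = sol[:r]
            if w.min() < -1e-12:
                continue
            full = np.zeros(m)
            full[S] = np.clip(w, 0.0, None)
            obj = 0.5 * full @ H @ full
            if obj < best_obj - 1e-15:
                best_obj, best = obj, full
    return best


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by enumerating every positive-negative pair (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


@pytest.fixture(scope="session")
def qp_oracle():
    return simplex_qp_oracle


@pytest.fixture(scope="session")
def auc_oracle():
    return brute_force_auc


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 40 x 20 planted-structure dataset for pipeline tests."""
    cfg = SimulationConfig(
        n_lnc=40, n_mir=20, n_groups=2, n_subgroups=2, seq_len_lnc=200,
        seq_len_mir=22, seed=3,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    X_lnc = kmer_features(small_dataset.lnc_records, 3)
    X_mir = kmer_features(small_dataset.mir_records, 3)
    return X_lnc, X_mir


@pytest.fixture(scope="session")
def study_dataset():
    """The full-size study conditions (120 x 60, 4 groups, seed 7)."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def study_features(study_dataset):
    X_lnc = kmer_features(study_dataset.lnc_records, 5)
    X_mir = kmer_features(study_dataset.mir_records, 5)
    return X_lnc, X_mir
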