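"""k-mer frequency features for nucleotide sequences.

Every lncRNA/miRNA sequence is represented by the occurrence frequencies
of all 4^k contiguous length-k subsequences (overlapping windows, step 1).
U and T are treated as the same symbol, so RNA and DNA spellings of the
same transcript yield identical features.  Windows containing the
ambiguity code N are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .data_io import SequenceRecord

_BASE_ORDER = "ACGT"  # lexicographic order defining feature columns
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": -1}


@dataclass
class FeatureMatrix:
    """Entities-by-features matrix with aligned id and feature-name lists."""

    X: np.ndarray
    entity_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.entity_ids), len(self.feature_names)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.entity_ids)} ids x {len(self.feature_names)} features"
            )


def kmer_names(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order over A < C < G < T."""
    return ["".join(p) for p in product(_BASE_ORDER, repeat=k)]


def _count_kmers(sequence: str, k: int) -> np.ndarray:
    codes = np.array([_CODE[c] for c in sequence], dtype=np.int64)
    n_windows = len(codes) - k + 1
    if n_windows <= 0:
        return np.zeros(4**k)
    # base-4 code of each window; windows touching an N (-1) are dropped
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmer_codes = windows[valid] @ powers
    return np.bincount(kmer_codes, minlength=4**k).astype(float)


def kmer_features(records: Sequence[SequenceRecord], k: int = 5) -> FeatureMatrix:
    """Compute the k-mer frequency matrix for a list of sequence records.

    Each row is the count of every length-k window divided by the number
    of counted windows, so rows sum to 1.  A sequence with no countable
    window (shorter than k once N-containing windows are excluded) raises
    ``ValueError`` naming the record.
    """
    if k <= 0:
        raise ValueError(f"k must be a positive integer, got {k}")
    X = np.zeros((len(records), 4**k))
    for r, rec in enumerate(records):
        counts = _count_kmers(rec.sequence, k)
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"record {rec.id!r} has no countable {k}-mer window "
                f"(length {len(rec.sequence)}, N windows excluded)"
            )
        X[r] = counts / total
    return FeatureMatrix(X, [r.id for r in records], kmer_names(k))
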