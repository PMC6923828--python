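"""Input/output for sequences, interaction lists and matrix tables.

The on-disk formats are deliberately plain: FASTA for sequences, a
two-column TSV for the known-interaction list, header-ed TSV for feature /
similarity matrices, and a four-column TSV for ranked predictions.  All
entity bookkeeping (mapping external ids to matrix row/column indices) is
done here so the numerical modules only ever see aligned dense arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# A, C, G, T plus U (RNA) and the ambiguity code N; anything else is an error.
_VALID_CHARS = frozenset("ACGTUN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (DNA or RNA alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}; "
                "allowed alphabet is A/C/G/T/U plus N"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class InteractionMatrix:
    """Binary lncRNA x miRNA interaction matrix with ordered id lists.

    ``Y[i, j] == 1`` iff lncRNA ``lnc_ids[i]`` is known to interact with
    miRNA ``mir_ids[j]``.
    """

    Y: np.ndarray
    lnc_ids: list[str]
    mir_ids: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix")
        if self.Y.shape != (len(self.lnc_ids), len(self.mir_ids)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match id lists "
                f"({len(self.lnc_ids)} x {len(self.mir_ids)})"
            )
        for name, ids in (("lnc_ids", self.lnc_ids), ("mir_ids", self.mir_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate ids in {name}")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("Y must be binary (0/1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(self.Y.copy(), list(self.lnc_ids), list(self.mir_ids))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; duplicate ids, empty sequences and characters
    outside the A/C/G/T/U/N alphabet raise ``ValueError`` naming the
    offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records and path.stat().st_size > 0:
        raise ValueError(f"{path} contains no parseable FASTA records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving order."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_interactions(
    path: str | Path,
    lnc_ids: Sequence[str],
    mir_ids: Sequence[str],
    strict: bool = True,
) -> InteractionMatrix:
    """Read a two-column (lncRNA id, miRNA id) TSV into an interaction matrix.

    Duplicated pairs collapse to a single 1.  Pairs referencing an id not
    present in ``lnc_ids``/``mir_ids`` raise ``ValueError`` when
    ``strict`` (the default) or are skipped with a warning otherwise.
    """
    lnc_index = {x: i for i, x in enumerate(lnc_ids)}
    mir_index = {x: j for j, x in enumerate(mir_ids)}
    Y = np.zeros((len(lnc_ids), len(mir_ids)))
    pairs = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if pairs.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    for lnc, mir in pairs.iloc[:, :2].itertuples(index=False):
        if lnc not in lnc_index or mir not in mir_index:
            msg = f"interaction pair ({lnc!r}, {mir!r}) references an unknown id"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; skipped", stacklevel=2)
            continue
        Y[lnc_index[lnc], mir_index[mir]] = 1.0
    return InteractionMatrix(Y, list(lnc_ids), list(mir_ids))


def write_interactions(interactions: InteractionMatrix, path: str | Path) -> None:
    """Write the positive pairs of an interaction matrix as two-column TSV.

    Rows are sorted by (lncRNA id, miRNA id) so output is deterministic.
    """
    rows = [
        (interactions.lnc_ids[i], interactions.mir_ids[j])
        for i, j in np.argwhere(interactions.Y == 1.0)
    ]
    rows.sort()
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_predictions(
    predictions,
    path: str | Path,
    known: InteractionMatrix | None = None,
    mask_known: bool = False,
) -> None:
    """Write a ranked prediction table.

    Columns are (lncRNA_id, miRNA_id, score, known_flag), sorted by
    descending score with ties broken lexicographically on the id pair.
    ``known`` marks the training positives; with ``mask_known`` those
    pairs are removed from the ranking entirely.
    """
    P = np.asarray(predictions.P, dtype=float)
    lnc_ids, mir_ids = predictions.lnc_ids, predictions.mir_ids
    if mask_known and known is None:
        raise ValueError("mask_known requires the training interaction matrix")
    known_mat = (
        known.Y.astype(bool)
        if known is not None
        else np.zeros(P.shape, dtype=bool)
    )
    if known is not None and known_mat.shape != P.shape:
        raise ValueError("known interactions not aligned with predictions")
    rows = []
    for i, lnc in enumerate(lnc_ids):
        for j, mir in enumerate(mir_ids):
            if mask_known and known_mat[i, j]:
                continue
            rows.append((lnc, mir, P[i, j], int(known_mat[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    df = pd.DataFrame(rows, columns=["lncRNA_id", "miRNA_id", "score", "known_flag"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_matrix(
    M: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a labelled dense matrix as TSV with a header row and index column."""
    pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix back as (values, row ids, column ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index], [str(c) for c in df.columns]
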