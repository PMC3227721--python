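"""Both-strand matrix scanning and hit tallying.

`scan_sequence` slides a frequency matrix along a DNA sequence and
reports every window whose matrix-similarity score reaches a cutoff.
Minus-strand sites are found by scanning with the reverse-complement
matrix and are reported in plus-strand coordinates with strand "-".
Windows containing N are skipped.  `build_presence_matrix` tallies hits
into a binding-site-identity x sequence count table — the structure used
to compare regulatory sequences sharing an expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError
from .motif_model import (
    FrequencyMatrix,
    _accumulate_scores,
    encode,
    reverse_complement_matrix,
)

logger = logging.getLogger(__name__)

STRAND_CHOICES = ("+", "-", "both")


@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    sequence_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not set(self.residues) <= set("ACGTN"):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise ValueError(
                f"sequence {self.sequence_id!r}: invalid symbols {bad}; "
                "use interfaces.read_fasta to normalise raw input"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        from .motif_model import reverse_complement

        return SequenceRecord(self.sequence_id, reverse_complement(self.residues))


@dataclass(frozen=True)
class MotifHit:
    """One predicted binding site, in plus-strand 0-based half-open coords."""

    sequence_id: str
    matrix_id: str
    tf_class: str
    start: int
    end: int
    strand: str
    score: float

    def identity(self, level: str) -> str:
        if level == "class":
            return self.tf_class
        if level == "consensus":
            return self.matrix_id
        raise ValueError(f"unknown aggregation level {level!r}")


def window_scores(seq: SequenceRecord, matrix: FrequencyMatrix) -> np.ndarray:
    """Plus-strand matrix-similarity scores for every window of `seq`.

    Windows containing N get NaN.  Returns an empty array when the
    sequence is shorter than the matrix.
    """
    L = matrix.length
    n = seq.length - L + 1
    if n <= 0:
        return np.empty(0, dtype=float)
    codes = encode(seq.residues)
    weights, smin, smax = matrix._scoring_arrays()
    # a window starting at o is valid iff codes[o:o+L] has no 4 (N)
    is_n = (codes == 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cum[L:] - cum[:-L]) == 0
    safe_codes = np.where(codes == 4, 0, codes)
    if smax == smin:  # wholly uninformative matrix: every valid window scores 1
        scores = np.ones(n, dtype=float)
    else:
        raw = _accumulate_scores(weights, safe_codes, n)
        scores = (raw - smin) / (smax - smin)
    scores[~valid] = np.nan
    if not valid.all():
        logger.debug(
            "sequence %s: skipped %d windows containing N for matrix %s",
            seq.sequence_id, int((~valid).sum()), matrix.matrix_id,
        )
    return scores


def scan_sequence(
    seq: SequenceRecord,
    matrix: FrequencyMatrix,
    cutoff: float,
    strands: str = "both",
) -> list[MotifHit]:
    """All matches of `matrix` in `seq` with score >= cutoff.

    Parameters
    ----------
    cutoff : float in [0, 1]
        Matrix-similarity score threshold.
    strands : "+", "-" or "both"
        Which strands to search.  Minus-strand hits are reported in
        plus-strand coordinates with strand "-".

    Returns hits sorted by start position, then strand ("+" first).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if strands not in STRAND_CHOICES:
        raise ValueError(f"strands must be one of {STRAND_CHOICES}, got {strands!r}")
    L = matrix.length
    hits: list[MotifHit] = []
    if strands in ("+", "both"):
        scores = window_scores(seq, matrix)
        for o in np.nonzero(scores >= cutoff)[0]:
            hits.append(
                MotifHit(seq.sequence_id, matrix.matrix_id, matrix.tf_class,
                         int(o), int(o) + L, "+", float(scores[o]))
            )
    if strands in ("-", "both"):
        rc = reverse_complement_matrix(matrix)
        scores = window_scores(seq, rc)
        for o in np.nonzero(scores >= cutoff)[0]:
            hits.append(
                MotifHit(seq.sequence_id, matrix.matrix_id, matrix.tf_class,
                         int(o), int(o) + L, "-", float(scores[o]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_sequences(
    sequences: Sequence[SequenceRecord],
    matrices: Sequence[FrequencyMatrix],
    cutoffs: "float | dict[str, float]",
    strands: str = "both",
) -> list[MotifHit]:
    """Scan every sequence with every matrix; per-matrix cutoffs allowed."""
    hits: list[MotifHit] = []
    for seq in sequences:
        for m in matrices:
            c = cutoffs[m.matrix_id] if isinstance(cutoffs, dict) else cutoffs
            hits.extend(scan_sequence(seq, m, c, strands=strands))
    return hits


@dataclass
class PresenceMatrix:
    """Hit-count table: binding-site identities (rows) x sequences (columns).

    `level` records whether rows are TF classes ("class") or individual
    matrix consensus patterns ("consensus").  The underlying table is a
    pandas DataFrame of nonnegative integers.
    """

    level: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("class", "consensus"):
            raise ValueError(f"unknown presence level {self.level!r}")
        if (self.table.values < 0).any():
            raise ValueError("presence counts must be nonnegative")
        self.table = self.table.astype(int)

    @property
    def row_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.values


def build_presence_matrix(
    hits: Iterable[MotifHit],
    level: str,
    column_ids: Sequence[str],
    row_universe: Optional[Sequence[str]] = None,
) -> PresenceMatrix:
    """Tally hits into a PresenceMatrix.

    Every hit's sequence_id must appear in `column_ids`.  Rows that are
    zero across all columns are dropped, unless a fixed `row_universe`
    is supplied, in which case exactly those rows appear in that order.
    """
    columns = list(column_ids)
    col_index = {c: j for j, c in enumerate(columns)}
    counts: dict[str, np.ndarray] = {}
    for hit in hits:
        if hit.sequence_id not in col_index:
            raise ConsistencyError(
                f"hit references sequence {hit.sequence_id!r} absent from column_ids"
            )
        row = hit.identity(level)
        if row not in counts:
            counts[row] = np.zeros(len(columns), dtype=int)
        counts[row][col_index[hit.sequence_id]] += 1
    if row_universe is not None:
        rows = list(row_universe)
    else:
        rows = sorted(counts)
    data = np.zeros((len(rows), len(columns)), dtype=int)
    for i, r in enumerate(rows):
        if r in counts:
            data[i] = counts[r]
    table = pd.DataFrame(data, index=pd.Index(rows, name="binding_site"), columns=columns)
    return PresenceMatrix(level=level, table=table)
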