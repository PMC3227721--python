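"""Position-frequency matrix models and matrix-similarity scoring.

A transcription-factor binding site is modelled as a position-frequency
matrix (PFM): per position, counts (or frequencies) of A, C, G and T
observed in known instances of the site.  Windows of DNA are scored with
an information-weighted matrix-similarity score (MSS) normalised to
[0, 1]: 1 on the best possible match to the matrix (its consensus), 0 on
the worst.  Positions with little information content (near-uniform
frequency rows) contribute little to the score, so the score is driven
by the conserved core of the site.

The score of a window ``w`` of length ``L`` is

    S(w)  = sum_i I(i) * f(i, w_i)
    MSS(w) = (S(w) - S_min) / (S_max - S_min)

where ``f(i, b)`` is the frequency of base ``b`` at position ``i``,
``I(i) = sum_b f(i, b) ln(4 f(i, b))`` is the information vector
(0 for a uniform row, ln 4 for a single-base row) and ``S_min``/``S_max``
use the per-position minimum/maximum frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import AmbiguousBaseError, DegenerateMatrixError

ALPHABET = "ACGT"
LN4 = float(np.log(4.0))

# base -> column index; everything else (incl. N) -> 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0, C=1, G=2, T=3, other=4."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(eq=False)
class FrequencyMatrix:
    """A binding-site frequency matrix with its TF-class label.

    Parameters
    ----------
    matrix_id : str
        Accession of the matrix (e.g. ``M00979``).
    tf_name : str
        Name of the transcription factor the matrix models.
    tf_class : str
        Family label used to pool hit counts across related matrices
        (e.g. ``Pax6``, ``pbx-1b``).  Must be non-empty.
    counts : array-like, shape (L, 4)
        Nonnegative per-position counts ordered A, C, G, T.  Already
        normalised frequency rows are accepted: counts are rescaled to
        frequencies either way.
    pseudocount : float
        Added to every count before deriving frequencies; the default
        0.01 keeps every frequency strictly positive so the
        anti-consensus score is well defined.
    """

    matrix_id: str
    tf_name: str
    tf_class: str
    counts: np.ndarray
    pseudocount: float = 0.01
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError(
                f"matrix {self.matrix_id!r}: counts must have shape (L>=1, 4), "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"matrix {self.matrix_id!r}: negative counts")
        if self.pseudocount < 0:
            raise ValueError(f"matrix {self.matrix_id!r}: negative pseudocount")
        if not self.tf_class:
            raise ValueError(f"matrix {self.matrix_id!r}: empty tf_class")
        if np.any(self.counts.sum(axis=1) + 4 * self.pseudocount <= 0):
            raise DegenerateMatrixError(
                f"matrix {self.matrix_id!r}: all-zero position with pseudocount 0"
            )

    # -- derived quantities --------------------------------------------------

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-position probability rows, each summing to 1."""
        if "freq" not in self._cache:
            self._cache["freq"] = derive_frequencies(self)
        return self._cache["freq"]

    @property
    def information(self) -> np.ndarray:
        """Per-position information weights I(i) in [0, ln 4] nats."""
        if "info" not in self._cache:
            self._cache["info"] = information_vector(self.frequencies)
        return self._cache["info"]

    @property
    def consensus(self) -> str:
        """Per-position argmax base string (ties -> first of A,C,G,T)."""
        return "".join(ALPHABET[j] for j in np.argmax(self.frequencies, axis=1))

    def _scoring_arrays(self) -> tuple[np.ndarray, float, float]:
        """(weights W = I[:,None]*f, S_min, S_max) used by the score kernel."""
        if "weights" not in self._cache:
            f = self.frequencies
            info = self.information
            w = info[:, None] * f
            smin = float(np.sum(info * f.min(axis=1)))
            smax = float(np.sum(info * f.max(axis=1)))
            self._cache["weights"] = (w, smin, smax)
        return self._cache["weights"]

    def score_window(self, window: str) -> float:
        return score_window(self, window)

    def reverse_complement(self) -> "FrequencyMatrix":
        return reverse_complement_matrix(self)


def derive_frequencies(matrix: FrequencyMatrix) -> np.ndarray:
    """Pseudocount-smoothed per-position probability rows.

    ``f(i, b) = (count(i, b) + pc) / sum_b' (count(i, b') + pc)``.
    """
    smoothed = matrix.counts + matrix.pseudocount
    totals = smoothed.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateMatrixError(
            f"matrix {matrix.matrix_id!r}: all-zero position with pseudocount 0"
        )
    return smoothed / totals


def information_vector(frequencies: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4 f), in nats.

    0 * ln 0 is taken as 0, so I(i) ranges from 0 (uniform row) to ln 4
    (single-base row).
    """
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=1)


def _accumulate_scores(weights: np.ndarray, codes: np.ndarray, n_windows: int) -> np.ndarray:
    """Raw S for all windows, accumulated position-by-position.

    The sequential accumulation order is the bit-exactness contract shared
    by the single-window scorer and the vectorised scanner.
    """
    acc = np.zeros(n_windows, dtype=float)
    for i in range(weights.shape[0]):
        acc += weights[i, codes[i : i + n_windows]]
    return acc


def score_window(matrix: FrequencyMatrix, window: str) -> float:
    """Normalised matrix-similarity score of one L-mer, in [0, 1].

    Raises :class:`AmbiguousBaseError` on non-ACGT symbols; the scanner
    is responsible for skipping such windows.
    """
    if len(window) != matrix.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {matrix.length}"
        )
    codes = encode(window)
    if np.any(codes == 4):
        raise AmbiguousBaseError(f"window {window!r} contains a non-ACGT symbol")
    weights, smin, smax = matrix._scoring_arrays()
    if smax == smin:  # every position uninformative
        return 1.0
    raw = _accumulate_scores(weights, codes, 1)[0]
    return (raw - smin) / (smax - smin)


def reverse_complement_matrix(matrix: FrequencyMatrix) -> FrequencyMatrix:
    """Matrix modelling the same sites read on the opposite strand.

    Positions are reversed and the A/T and C/G columns swapped; applying
    the operation twice returns the original.  For any window ``w``,
    ``score(rc_matrix, rc(w)) == score(matrix, w)``.
    """
    rc_counts = matrix.counts[::-1, ::-1].copy()
    return FrequencyMatrix(
        matrix_id=matrix.matrix_id,
        tf_name=matrix.tf_name,
        tf_class=matrix.tf_class,
        counts=rc_counts,
        pseudocount=matrix.pseudocount,
    )


def matrices_by_class(matrices: Iterable[FrequencyMatrix]) -> dict[str, list[FrequencyMatrix]]:
    """Group matrices by tf_class, preserving input order within a class."""
    out: dict[str, list[FrequencyMatrix]] = {}
    for m in matrices:
        out.setdefault(m.tf_class, []).append(m)
    return out
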