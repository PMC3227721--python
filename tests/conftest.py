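"""Shared fixtures and independent oracle scorers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ciscompare import FrequencyMatrix, SequenceRecord

ALPHABET = "ACGT"


def oracle_score(counts: np.ndarray, pseudocount: float, window: str) -> float:
    """Independent reimplementation of the matrix-similarity score.

    Recomputes frequencies, information weights and normalisation from
    raw counts, then accumulates the window score position by position.
    Kept free of any ciscompare scoring code so it can serve as the
    brute-force oracle.
    """
    smoothed = np.asarray(counts, float) + pseudocount
    f = smoothed / smoothed.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    info = terms.sum(axis=1)
    w = info[:, None] * f
    smin = np.sum(info * f.min(axis=1))
    smax = np.sum(info * f.max(axis=1))
    if smax == smin:
        return 1.0
    s = 0.0
    for i, ch in enumerate(window):
        s += w[i, ALPHABET.index(ch)]
    return (s - smin) / (smax - smin)


def oracle_scan(seq: str, counts: np.ndarray, pseudocount: float, cutoff: float):
    """Exhaustive per-window brute-force scan on both strands.

    Returns a set of (start, end, strand, score) tuples; minus-strand
    scores come from the reverse-complemented count matrix applied in
    plus-strand coordinates.
    """
    counts = np.asarray(counts, float)
    L = counts.shape[0]
    rc_counts = counts[::-1, ::-1]
    out = set()
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        for strand, c in (("+", counts), ("-", rc_counts)):
            score = oracle_score(c, pseudocount, window)
            if score >= cutoff:
                out.add((start, start + L, strand, score))
    return out


def random_matrix(rng: np.random.Generator, length: int, matrix_id: str = "MR001",
                  tf_class: str = "RND", pseudocount: float = 0.01) -> FrequencyMatrix:
    counts = rng.integers(0, 20, size=(length, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1  # no all-zero rows
    return FrequencyMatrix(matrix_id, "random", tf_class, counts, pseudocount)


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "s1") -> SequenceRecord:
    return SequenceRecord(seq_id, "".join(rng.choice(list(ALPHABET), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
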