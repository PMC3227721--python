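"""Synthetic matrices, background DNA and planted-motif datasets.

Real calibration inputs for this kind of analysis — curated binding-site
collections and the enhancer fragments they are searched in — are
typically proprietary or unpublished, so this module generates stand-ins
with known ground truth: background sequences of configurable
composition (i.i.d. or first-order Markov), frequency matrices of
configurable length and information content, and sequences with motif
instances planted at recorded positions and strands.  Every generator is
deterministic under a fixed seed, which makes end-to-end recovery
experiments (plant, calibrate, scan, compare) reproducible tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .exceptions import ParameterError, PlacementError
from .motif_model import ALPHABET, LN4, FrequencyMatrix, reverse_complement
from .scanner import MotifHit, SequenceRecord

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted motif instance."""

    sequence_id: str
    start: int
    end: int
    strand: str
    matrix_id: str


@dataclass
class SyntheticDataset:
    """Sequences plus the ground truth of every planted site."""

    sequences: list[SequenceRecord]
    truth: list[PlantedSite]
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {s.sequence_id: s.length for s in self.sequences}
        by_seq: dict[str, list[PlantedSite]] = {}
        for t in self.truth:
            if t.sequence_id not in lengths:
                raise ValueError(f"truth references unknown sequence {t.sequence_id!r}")
            if not (0 <= t.start < t.end <= lengths[t.sequence_id]):
                raise ValueError(f"truth interval out of bounds: {t}")
            by_seq.setdefault(t.sequence_id, []).append(t)
        for sid, sites in by_seq.items():
            sites = sorted(sites, key=lambda t: t.start)
            for a, b in zip(sites, sites[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping truth intervals in {sid!r}")


def generate_background(
    n_sequences: int,
    length: int,
    composition: Optional[Sequence[float]] = None,
    transition: Optional[np.ndarray] = None,
    seed: RngLike = None,
    id_prefix: str = "bg",
) -> list[SequenceRecord]:
    """Random DNA sequences, i.i.d. or first-order Markov.

    Parameters
    ----------
    composition : length-4 probabilities (A, C, G, T) or None
        Base composition for i.i.d. sampling (None = uniform).  Ignored
        when `transition` is given, except as the initial-state
        distribution.
    transition : (4, 4) row-stochastic matrix or None
        First-order Markov transition probabilities; rows/columns
        ordered A, C, G, T.
    """
    if length < 1 or n_sequences < 1:
        raise ParameterError("n_sequences and length must be >= 1")
    comp = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ParameterError(f"composition must be 4 nonnegative numbers summing to 1, got {comp}")
    rng = _rng(seed)
    records = []
    if transition is not None:
        trans = np.asarray(transition, float)
        if trans.shape != (4, 4) or np.any(trans < 0) or np.any(np.abs(trans.sum(axis=1) - 1) > 1e-9):
            raise ParameterError("transition must be a (4,4) row-stochastic matrix")
        cum = np.cumsum(trans, axis=1)
        for k in range(n_sequences):
            codes = np.empty(length, dtype=np.int64)
            codes[0] = rng.choice(4, p=comp)
            u = rng.random(length)
            for i in range(1, length):
                codes[i] = np.searchsorted(cum[codes[i - 1]], u[i], side="right")
            records.append(SequenceRecord(f"{id_prefix}{k}", _decode(codes)))
    else:
        for k in range(n_sequences):
            codes = rng.choice(4, size=length, p=comp)
            records.append(SequenceRecord(f"{id_prefix}{k}", _decode(codes)))
    return records


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def sample_site(matrix: FrequencyMatrix, seed: RngLike = None) -> str:
    """Draw one L-mer position-by-position from the matrix frequencies."""
    rng = _rng(seed)
    freq = matrix.frequencies
    return "".join(ALPHABET[rng.choice(4, p=freq[i])] for i in range(matrix.length))


def sample_sites(matrix: FrequencyMatrix, n: int, seed: RngLike = None) -> list[str]:
    rng = _rng(seed)
    return [sample_site(matrix, rng) for _ in range(n)]


def plant_motifs(
    background: Sequence[SequenceRecord],
    matrix: FrequencyMatrix,
    n_sites: int,
    strand_policy: str = "both",
    seed: RngLike = None,
    max_retries: int = 1000,
) -> SyntheticDataset:
    """Plant `n_sites` sampled motif instances in each background sequence.

    Placement positions are drawn uniformly and rejected on overlap with
    already-placed sites (retry cap `max_retries` per sequence, then
    :class:`PlacementError`).  With strand_policy "both" each site lands
    on a uniformly chosen strand; minus-strand sites are written as the
    reverse complement of the sampled L-mer.  Ground truth records every
    placement.
    """
    if strand_policy not in ("+", "-", "both"):
        raise ParameterError(f"strand_policy must be '+', '-' or 'both', got {strand_policy!r}")
    if n_sites < 0:
        raise ParameterError("n_sites must be >= 0")
    rng = _rng(seed)
    L = matrix.length
    sequences: list[SequenceRecord] = []
    truth: list[PlantedSite] = []
    for rec in background:
        if n_sites * L > rec.length:
            raise PlacementError(
                f"cannot place {n_sites} non-overlapping sites of length {L} "
                f"in sequence {rec.sequence_id!r} of length {rec.length}"
            )
        placed: list[tuple[int, int]] = []
        residues = list(rec.residues)
        retries = 0
        while len(placed) < n_sites:
            start = int(rng.integers(0, rec.length - L + 1))
            if any(start < e and s < start + L for s, e in placed):
                retries += 1
                if retries > max_retries:
                    raise PlacementError(
                        f"sequence {rec.sequence_id!r}: exceeded {max_retries} placement retries"
                    )
                continue
            site = sample_site(matrix, rng)
            if strand_policy == "both":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = strand_policy
            written = site if strand == "+" else reverse_complement(site)
            residues[start : start + L] = written
            placed.append((start, start + L))
            truth.append(PlantedSite(rec.sequence_id, start, start + L, strand, matrix.matrix_id))
        sequences.append(SequenceRecord(rec.sequence_id, "".join(residues)))
    return SyntheticDataset(
        sequences=sequences,
        truth=sorted(truth, key=lambda t: (t.sequence_id, t.start)),
        generator_params={
            "matrix_id": matrix.matrix_id,
            "n_sites": n_sites,
            "strand_policy": strand_policy,
            "lengths": [r.length for r in background],
        },
    )


def _info_of_p(p: float) -> float:
    """Information of the row (p, q, q, q) with q = (1 - p) / 3."""
    q = (1.0 - p) / 3.0
    val = p * np.log(4.0 * p) if p > 0 else 0.0
    if q > 0:
        val += 3.0 * q * np.log(4.0 * q)
    return float(val)


def generate_matrix(
    length: int,
    target_information: float,
    seed: RngLike = None,
    matrix_id: str = "SYN0001",
    tf_name: str = "synthetic",
    tf_class: str = "SYN",
    jitter: float = 0.0,
) -> FrequencyMatrix:
    """Random matrix whose mean per-position information hits a target.

    Each position gets a randomly chosen consensus base with probability
    p and the remaining mass split evenly; p is solved so the position's
    information (in nats) meets `target_information`.  With the default
    ``jitter=0`` every position carries the target exactly, which gives
    the matrix a discrete, well-separated score distribution (score
    bands by mismatch count); a positive jitter spreads per-position
    targets uniformly within ``target*(1 +/- jitter)`` (mean rescaled
    back to the target) for a rougher, more natural profile.  The mean
    information is within 5% of the target either way; target must lie
    in (0, ln 4].
    """
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0.0 < target_information <= LN4 + 1e-12:
        raise ParameterError(
            f"target information must be in (0, ln4={LN4:.4f}], got {target_information}"
        )
    if not 0.0 <= jitter < 1.0:
        raise ParameterError(f"jitter must be in [0, 1), got {jitter}")
    rng = _rng(seed)
    if jitter > 0:
        # jitter per-position targets, then rescale so the mean is exact
        targets = target_information * rng.uniform(1 - jitter, 1 + jitter, size=length)
        targets *= target_information / targets.mean()
        targets = np.clip(targets, 1e-4, LN4)
    else:
        targets = np.full(length, target_information)
    rows = np.empty((length, 4), dtype=float)
    for i in range(length):
        t = float(targets[i])
        if t >= LN4 - 1e-9:
            p = 1.0
        else:
            p = brentq(lambda x: _info_of_p(x) - t, 0.25 + 1e-12, 1.0 - 1e-12)
        q = (1.0 - p) / 3.0
        row = np.full(4, q)
        row[rng.integers(0, 4)] = p
        rows[i] = row
    m = FrequencyMatrix(
        matrix_id=matrix_id,
        tf_name=tf_name,
        tf_class=tf_class,
        counts=rows * 100.0,
        pseudocount=0.0,
    )
    mean_info = float(m.information.mean())
    if abs(mean_info - target_information) > 0.05 * target_information:
        raise ParameterError(
            f"generated mean information {mean_info:.4f} misses target "
            f"{target_information:.4f} by more than 5% (clipping at ln 4?)"
        )
    return m


def score_recovery(
    hits: Sequence[MotifHit],
    truth: Sequence[PlantedSite],
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """(sensitivity, false discovery proportion) of a scan against truth.

    A hit matches a planted site when they lie on the same sequence and
    strand and their reciprocal overlap is at least `min_overlap` of
    each interval.  Sensitivity is the fraction of planted sites matched
    by at least one hit; the false discovery proportion is the fraction
    of hits matching no planted site.
    """
    def overlaps(h: MotifHit, t: PlantedSite) -> bool:
        if h.sequence_id != t.sequence_id or h.strand != t.strand:
            return False
        inter = min(h.end, t.end) - max(h.start, t.start)
        return inter >= min_overlap * (h.end - h.start) and inter >= min_overlap * (t.end - t.start)

    matched_truth = sum(1 for t in truth if any(overlaps(h, t) for h in hits))
    sensitivity = matched_truth / len(truth) if truth else float("nan")
    if hits:
        false_hits = sum(1 for h in hits if not any(overlaps(h, t) for t in truth))
        fdp = false_hits / len(hits)
    else:
        fdp = 0.0
    return sensitivity, fdp
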