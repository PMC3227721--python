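"""Per-matrix cutoff calibration: minFN10, minFP and minSum.

A scanning cutoff trades sensitivity against specificity.  Calibration
takes a set of known true binding sites (L-mers) and a set of background
sequences, sweeps a cutoff grid over [0, 1] and derives three named
cutoffs per matrix:

* ``minFN10`` — the largest cutoff that still recovers at least 90% of
  the true sites (at most 10% false negatives).  The number of
  background matches at this cutoff defines the 100% false-positive
  baseline.
* ``minFP`` — the smallest cutoff in [minFN10, 1] at which the
  background match count reaches its minimum over that range (usually
  zero); it is the high-specificity end of the sweep.
* ``minSum`` — the cutoff in [minFN10, minFP] minimising FN% + FP%,
  the balanced-error setting; ties resolve to the smallest (most
  sensitive) cutoff.

By construction ``minFN10 <= minSum <= minFP`` and the FN%/FP% curves
are monotone in the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ConfigError
from .motif_model import FrequencyMatrix, score_window
from .scanner import SequenceRecord, window_scores

logger = logging.getLogger(__name__)

CUTOFF_MODES = ("minFN10", "minSum", "minFP")
DEFAULT_GRID_STEP = 0.005


@dataclass
class CutoffProfile:
    """Calibration result for one matrix.

    fn_percent[i] is the percentage of true sites scoring below grid[i];
    fp_percent[i] is the background match count at grid[i] as a
    percentage of the count at the minFN10 cutoff (identically 0 when no
    background match exists at minFN10).  bg_counts keeps the raw
    background match counts behind fp_percent.
    """

    matrix_id: str
    grid: np.ndarray
    fn_percent: np.ndarray
    fp_percent: np.ndarray
    bg_counts: np.ndarray
    cutoff_min_fn10: float
    cutoff_min_fp: float
    cutoff_min_sum: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fn_percent) < 0):
            raise CalibrationError("FN% curve is not non-decreasing")
        if np.any(np.diff(self.fp_percent) > 0):
            raise CalibrationError("FP% curve is not non-increasing")
        if not (self.cutoff_min_fn10 <= self.cutoff_min_sum <= self.cutoff_min_fp):
            raise CalibrationError(
                "cutoff ordering violated: "
                f"{self.cutoff_min_fn10} <= {self.cutoff_min_sum} <= {self.cutoff_min_fp}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.grid,
                "fn_percent": self.fn_percent,
                "fp_percent": self.fp_percent,
                "bg_matches": self.bg_counts,
            }
        )

    def summary(self) -> dict:
        return {
            "matrix_id": self.matrix_id,
            "minFN10": self.cutoff_min_fn10,
            "minSum": self.cutoff_min_sum,
            "minFP": self.cutoff_min_fp,
        }


def calibrate_cutoffs(
    matrix: FrequencyMatrix,
    true_sites: Sequence[str],
    background: Sequence[SequenceRecord],
    grid_step: float = DEFAULT_GRID_STEP,
) -> CutoffProfile:
    """Sweep the cutoff grid and derive minFN10/minSum/minFP.

    Parameters
    ----------
    true_sites : sequence of L-mers
        Known instances of the binding site; each must match the matrix
        length.  FN% at a cutoff is the fraction of these scoring below
        it.
    background : sequences
        Sequences assumed to contain no (or negligibly few) true sites;
        matches in them count as false positives.  Both strands are
        scanned.
    grid_step : float
        Spacing of the cutoff grid over [0, 1].
    """
    if len(true_sites) == 0:
        raise CalibrationError(f"matrix {matrix.matrix_id!r}: no true sites supplied")
    L = matrix.length
    scannable = sum(max(0, s.length - L + 1) for s in background)
    if scannable <= 0:
        raise CalibrationError(
            f"matrix {matrix.matrix_id!r}: background too short to scan (L={L})"
        )
    true_scores = np.sort([score_window(matrix, s) for s in true_sites])

    bg_parts = []
    for seq in background:
        for m in (matrix, matrix.reverse_complement()):
            sc = window_scores(seq, m)
            bg_parts.append(sc[~np.isnan(sc)])
    bg_scores = np.sort(np.concatenate(bg_parts)) if bg_parts else np.empty(0)

    n_grid = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n_grid + 1)

    # matches are score >= cutoff, so a true site is missed iff score < cutoff
    fn_percent = 100.0 * np.searchsorted(true_scores, grid, side="left") / len(true_scores)
    bg_counts = len(bg_scores) - np.searchsorted(bg_scores, grid, side="left")

    below = np.nonzero(fn_percent <= 10.0)[0]
    i10 = int(below[-1])  # largest grid cutoff keeping FN% <= 10

    baseline = int(bg_counts[i10])
    if baseline > 0:
        fp_percent = 100.0 * bg_counts / baseline
    else:
        fp_percent = np.zeros_like(grid)
        logger.warning(
            "matrix %s: no background match at minFN10 cutoff %.3f; FP%% set to 0",
            matrix.matrix_id, grid[i10],
        )

    tail = bg_counts[i10:]
    ifp = i10 + int(np.argmax(tail == tail.min()))  # smallest cutoff at the minimum

    sums = fn_percent[i10 : ifp + 1] + fp_percent[i10 : ifp + 1]
    isum = i10 + int(np.argmin(sums))  # argmin takes the first (smallest cutoff) tie

    return CutoffProfile(
        matrix_id=matrix.matrix_id,
        grid=grid,
        fn_percent=fn_percent,
        fp_percent=fp_percent,
        bg_counts=bg_counts.astype(int),
        cutoff_min_fn10=float(grid[i10]),
        cutoff_min_fp=float(grid[ifp]),
        cutoff_min_sum=float(grid[isum]),
    )


def apply_profile(matrix: FrequencyMatrix, profile: CutoffProfile, mode: str) -> float:
    """Return the calibrated cutoff selected by `mode` for `matrix`."""
    if profile.matrix_id != matrix.matrix_id:
        raise CalibrationError(
            f"profile for {profile.matrix_id!r} applied to matrix {matrix.matrix_id!r}"
        )
    if mode == "minFN10":
        return profile.cutoff_min_fn10
    if mode == "minSum":
        return profile.cutoff_min_sum
    if mode == "minFP":
        return profile.cutoff_min_fp
    raise ConfigError(f"unknown cutoff mode {mode!r}; expected one of {CUTOFF_MODES}")
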