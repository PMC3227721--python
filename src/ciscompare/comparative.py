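"""Common and differential binding sites across sequence groups.

Given a presence matrix (binding-site identities x sequences) and a
grouping of sequences by expression profile, extract the binding-site
identities present in every sequence of a positive group
(``common_sites``) and, among those, the ones additionally absent from
every sequence of a negative group (``differential_sites``).  This is
the reconciliation step that turns per-sequence motif scans into
candidate regulators of a shared expression territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

from .exceptions import ContrastError, VocabularyError
from .scanner import PresenceMatrix

logger = logging.getLogger(__name__)

#: Controlled vocabulary of expression-territory labels.  Ascidian larval
#: territories: SV sensory vesicle, VG visceral ganglion, NC nerve cord,
#: Ph pharynx, TSN tail sensory neurons.  Vertebrate: rhombomeres r4-r6,
#: hindbrain, NC_crest neural crest, ganglia_V_VIII cranial ganglia V/VIII.
TERRITORY_VOCABULARY = frozenset(
    {"SV", "VG", "NC", "Ph", "TSN", "r4", "r5", "r6", "NC_crest",
     "hindbrain", "ganglia_V_VIII"}
)


@dataclass(frozen=True)
class ExpressionAnnotation:
    """Expression territories recorded for one regulatory sequence."""

    sequence_id: str
    species: str
    territories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.territories) - TERRITORY_VOCABULARY
        if unknown:
            raise VocabularyError(
                f"sequence {self.sequence_id!r}: unknown territory labels {sorted(unknown)}"
            )


@dataclass(frozen=True)
class GroupContrast:
    """A positive sequence group and a disjoint (possibly empty) negative one."""

    positive_ids: frozenset[str]
    negative_ids: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.positive_ids:
            raise ContrastError(f"contrast {self.name!r}: empty positive group")
        overlap = self.positive_ids & self.negative_ids
        if overlap:
            raise ContrastError(
                f"contrast {self.name!r}: groups overlap on {sorted(overlap)}"
            )


def sequences_with_territory(
    annotations: Iterable[ExpressionAnnotation], territory: str
) -> set[str]:
    """IDs of sequences annotated as active in `territory`.

    This is a starting point for group definition, not the group itself:
    a sequence may carry a territory label for signal the original assay
    deemed ectopic, so curated contrasts may deliberately exclude it.
    """
    if territory not in TERRITORY_VOCABULARY:
        raise VocabularyError(f"unknown territory label {territory!r}")
    seen = set()
    out = set()
    for ann in annotations:
        if ann.sequence_id in seen:
            raise ValueError(f"duplicate annotation for {ann.sequence_id!r}")
        seen.add(ann.sequence_id)
        if territory in ann.territories:
            out.add(ann.sequence_id)
    return out


def _check_ids(matrix: PresenceMatrix, ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    missing = [i for i in ids if i not in matrix.table.columns]
    if missing:
        raise ContrastError(f"{what} sequences absent from presence matrix: {missing}")
    return ids


def common_sites(
    matrix: PresenceMatrix,
    positive_ids: Iterable[str],
    min_count: int = 1,
) -> set[str]:
    """Row identities with count >= min_count in every positive column."""
    ids = _check_ids(matrix, positive_ids, "positive")
    if not ids:
        raise ContrastError("empty positive group")
    sub = matrix.table[ids]
    mask = (sub >= min_count).all(axis=1)
    return set(sub.index[mask])


def differential_sites(
    matrix: PresenceMatrix,
    contrast: GroupContrast,
    min_count: int = 1,
    absent_max: int = 0,
) -> set[str]:
    """Common sites of the positive group with count <= absent_max in every
    negative column.

    With the defaults, "present" means at least one hit and "absent"
    means no hit at all — the presence/absence semantics of a
    qualitative motif-content comparison.
    """
    common = common_sites(matrix, contrast.positive_ids, min_count=min_count)
    neg = _check_ids(matrix, contrast.negative_ids, "negative")
    if not neg:
        return common
    sub = matrix.table.loc[sorted(common), neg]
    mask = (sub <= absent_max).all(axis=1)
    return set(sub.index[mask])


def restrict_rows(
    matrix: PresenceMatrix,
    row_filter: Union[Iterable[str], Callable[[str], bool]],
) -> PresenceMatrix:
    """Sub-matrix keeping the requested rows, column order preserved.

    `row_filter` is a set of row identities or a predicate on them.
    Requested rows missing from the matrix are logged as a warning, not
    an error.
    """
    if callable(row_filter):
        keep = [r for r in matrix.table.index if row_filter(r)]
    else:
        wanted = list(row_filter)
        if not wanted:
            raise ValueError("empty row filter")
        missing = [r for r in wanted if r not in matrix.table.index]
        if missing:
            logger.warning("requested rows absent from presence matrix: %s", missing)
        keep = [r for r in matrix.table.index if r in set(wanted)]
    return PresenceMatrix(level=matrix.level, table=matrix.table.loc[keep].copy())
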