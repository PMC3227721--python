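"""Readers and writers for the pipeline's file formats.

Matrices come in as TRANSFAC flat files (the accepted dialect is the
minimal subset: ``AC``, ``ID``/``NA``, an optional ``CL`` class line,
and a ``P0``-headed count block, records separated by ``//``; all other
two-letter fields are ignored).  Sequences come in as FASTA.  Hits go
out as BED6 and as a full-field TSV (1-based inclusive coordinates, the
usual convention of exported tables); presence matrices, calibration
profiles and expression-annotation tables travel as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .calibration import CutoffProfile
from .comparative import ExpressionAnnotation
from .exceptions import ConfigError, FastaError, TransfacFormatError
from .motif_model import ALPHABET, FrequencyMatrix
from .scanner import MotifHit, PresenceMatrix, SequenceRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# TRANSFAC flat-file matrices


def parse_transfac_flat(
    text: str,
    class_overrides: Optional[dict[str, str]] = None,
    pseudocount: float = 0.01,
) -> list[FrequencyMatrix]:
    """Parse TRANSFAC flat-file matrix records.

    The TF class is taken from the record's ``CL`` line, else from
    `class_overrides` keyed by accession, else falls back to the
    factor name (``NA``/``ID``) so the class label is never empty.
    Column order is taken from the ``P0`` header, which may permute
    A, C, G, T; counts are stored in A, C, G, T order regardless.

    Raises :class:`TransfacFormatError` naming the record and line on a
    missing ``P0`` header, ragged count rows or negative counts.
    """
    overrides = class_overrides or {}
    matrices: list[FrequencyMatrix] = []
    fields: dict[str, str] = {}
    rows: list[list[float]] = []
    col_order: Optional[list[int]] = None
    record_no = 1
    saw_content = False

    def finish(line_no: int) -> None:
        nonlocal fields, rows, col_order, record_no, saw_content
        if not saw_content:
            return
        acc = fields.get("AC", f"record-{record_no}")
        if col_order is None:
            raise TransfacFormatError(
                f"record {acc} (#{record_no}) before line {line_no}: missing P0 header"
            )
        counts = np.asarray(rows, dtype=float)
        if counts.shape[0] < 1:
            raise TransfacFormatError(
                f"record {acc} (#{record_no}) before line {line_no}: empty count block"
            )
        name = fields.get("NA") or fields.get("ID") or acc
        tf_class = fields.get("CL") or overrides.get(acc) or name
        matrices.append(
            FrequencyMatrix(
                matrix_id=acc,
                tf_name=name,
                tf_class=tf_class,
                counts=counts,
                pseudocount=pseudocount,
            )
        )
        fields, rows, col_order = {}, [], None
        record_no += 1
        saw_content = False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line == "XX":
            continue
        if line.startswith("//"):
            finish(line_no)
            continue
        tag = line[:2]
        if tag == "P0":
            letters = line[2:].split()
            if sorted(letters) != sorted(ALPHABET):
                raise TransfacFormatError(
                    f"record #{record_no}, line {line_no}: P0 header must list A C G T, "
                    f"got {letters}"
                )
            col_order = [letters.index(b) for b in ALPHABET]
            saw_content = True
            continue
        if tag[:1].isdigit():
            if col_order is None:
                acc = fields.get("AC", f"record-{record_no}")
                raise TransfacFormatError(
                    f"record {acc} (#{record_no}), line {line_no}: count row before P0 header"
                )
            parts = line.split()
            values = parts[1:5]
            # trailing consensus symbol is optional; anything beyond 4 numbers + symbol is ragged
            if len(parts) < 5 or len(parts) > 6:
                raise TransfacFormatError(
                    f"record {fields.get('AC', f'record-{record_no}')} (#{record_no}), "
                    f"line {line_no}: expected 4 counts per position, got {len(parts) - 1} fields"
                )
            try:
                nums = [float(v) for v in values]
            except ValueError as exc:
                raise TransfacFormatError(
                    f"record {fields.get('AC', f'record-{record_no}')} (#{record_no}), "
                    f"line {line_no}: non-numeric count: {exc}"
                ) from None
            if any(v < 0 for v in nums):
                raise TransfacFormatError(
                    f"record {fields.get('AC', f'record-{record_no}')} (#{record_no}), "
                    f"line {line_no}: negative count"
                )
            rows.append([nums[j] for j in col_order])
            saw_content = True
            continue
        if len(tag) == 2 and tag.isalpha() and (len(line) == 2 or line[2] == " "):
            fields[tag] = line[2:].strip()
            saw_content = True
    finish(line_no=len(text.splitlines()) + 1)
    return matrices


def read_transfac(path: PathLike, **kwargs) -> list[FrequencyMatrix]:
    return parse_transfac_flat(Path(path).read_text(), **kwargs)


def write_transfac(matrices: Iterable[FrequencyMatrix], handle_or_path: Union[PathLike, TextIO]) -> None:
    """Write matrices in the accepted TRANSFAC flat dialect (with CL lines)."""
    lines: list[str] = []
    for m in matrices:
        lines.append(f"AC  {m.matrix_id}")
        lines.append("XX")
        lines.append(f"ID  {m.tf_name}")
        lines.append("XX")
        lines.append(f"NA  {m.tf_name}")
        lines.append("XX")
        lines.append(f"CL  {m.tf_class}")
        lines.append("XX")
        lines.append("P0      A      C      G      T")
        for i, row in enumerate(m.counts, start=1):
            vals = "".join(f"{v:11.6g}" for v in row)
            lines.append(f"{i:02d}{vals}")
        lines.append("XX")
        lines.append("//")
    text = "\n".join(lines) + "\n"
    if hasattr(handle_or_path, "write"):
        handle_or_path.write(text)
    else:
        Path(handle_or_path).write_text(text)


# ---------------------------------------------------------------------------
# FASTA sequences


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read sequences, uppercasing residues and mapping non-ACGTN to N.

    Raises :class:`FastaError` on an empty file or duplicate IDs.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        cleaned = "".join(c if c in "ACGTN" else "N" for c in residues)
        n_mapped = sum(1 for a, b in zip(residues, cleaned) if a != b)
        if n_mapped:
            logger.warning(
                "%s: sequence %s: mapped %d non-ACGTN symbols to N", path, rec.id, n_mapped
            )
        records.append(SequenceRecord(rec.id, cleaned))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sequence_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hits


def write_hits_bed(hits: Iterable[MotifHit], path: PathLike) -> None:
    """BED6: name is matrix_id|tf_class, score rescaled to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            bed_score = int(round(min(max(h.score, 0.0), 1.0) * 1000))
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.matrix_id}|{h.tf_class}\t"
                f"{bed_score}\t{h.strand}\n"
            )


_HIT_COLUMNS = ["sequence_id", "matrix_id", "tf_class", "start", "end", "strand", "score"]


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Full-field hit table with 1-based inclusive start/end."""
    rows = [
        (h.sequence_id, h.matrix_id, h.tf_class, h.start + 1, h.end, h.strand, h.score)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


def write_hits_tsv(hits: Iterable[MotifHit], path: PathLike) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_hits_tsv(path: PathLike) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            sequence_id=str(r.sequence_id),
            matrix_id=str(r.matrix_id),
            tf_class=str(r.tf_class),
            start=int(r.start) - 1,
            end=int(r.end),
            strand=str(r.strand),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Presence matrices, profiles, annotations


def write_presence_tsv(matrix: PresenceMatrix, path: PathLike) -> None:
    table = matrix.table.copy()
    table.index.name = "binding_site"
    table.to_csv(path, sep="\t")


def read_presence_tsv(path: PathLike, level: str = "class") -> PresenceMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "binding_site"
    return PresenceMatrix(level=level, table=table)


def write_profiles_tsv(profiles: Iterable[CutoffProfile], path: PathLike) -> None:
    """One row per (matrix, grid cutoff), plus the three summary cutoffs."""
    frames = []
    for p in profiles:
        df = p.to_frame()
        df.insert(0, "matrix_id", p.matrix_id)
        df["minFN10"] = p.cutoff_min_fn10
        df["minSum"] = p.cutoff_min_sum
        df["minFP"] = p.cutoff_min_fp
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile_summaries(path: PathLike) -> dict[str, dict[str, float]]:
    """matrix_id -> {minFN10, minSum, minFP} from a profiles TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for mid, grp in df.groupby("matrix_id"):
        first = grp.iloc[0]
        out[str(mid)] = {
            "minFN10": float(first["minFN10"]),
            "minSum": float(first["minSum"]),
            "minFP": float(first["minFP"]),
        }
    return out


def read_annotations_tsv(path: PathLike) -> list[ExpressionAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sequence_id", "species", "territories"}
    if not required <= set(df.columns):
        raise ConfigError(f"{path}: annotation table must have columns {sorted(required)}")
    return [
        ExpressionAnnotation(
            sequence_id=r.sequence_id,
            species=r.species,
            territories=frozenset(t for t in str(r.territories).split(",") if t),
        )
        for r in df.itertuples()
    ]


def write_bed_truth(truth, path: PathLike) -> None:
    """Ground-truth planted sites as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.sequence_id}\t{t.start}\t{t.end}\t{t.matrix_id}\t0\t{t.strand}\n")
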