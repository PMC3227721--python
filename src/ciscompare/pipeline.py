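"""End-to-end pipeline: scan, tally, contrast, report.

`run_pipeline` ties the stages together the way a full comparative
analysis runs: read sequences and matrices, resolve a cutoff per matrix
(fixed or one of the calibrated modes), scan both strands, build the
presence matrix at the configured aggregation level, then evaluate every
configured contrast, writing per-sequence hit tables, the presence
matrix, per-contrast reports and a run manifest.  A run can also start
from a precomputed presence matrix and execute the comparative stage
only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__, io
from .comparative import common_sites, differential_sites
from .config import PipelineConfig
from .exceptions import CiscompareError, ConfigError
from .motif_model import FrequencyMatrix
from .scanner import MotifHit, PresenceMatrix, build_presence_matrix, scan_sequences

logger = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    name: str
    common: set[str]
    differential: set[str]


@dataclass
class RunResult:
    """In-memory artifacts of a pipeline run, plus where they were written."""

    output_dir: Path
    presence: PresenceMatrix
    hits: list[MotifHit] = field(default_factory=list)
    contrasts: list[ContrastResult] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _resolve_cutoffs(config: PipelineConfig, matrices: list[FrequencyMatrix]) -> dict[str, float]:
    if config.cutoff_mode == "fixed":
        return {m.matrix_id: float(config.cutoff_value) for m in matrices}
    summaries = io.read_profile_summaries(config.profiles)
    cutoffs = {}
    for m in matrices:
        if m.matrix_id not in summaries:
            raise ConfigError(f"no calibrated profile for matrix {m.matrix_id!r}")
        cutoffs[m.matrix_id] = summaries[m.matrix_id][config.cutoff_mode]
    return cutoffs


def _select_non_redundant(matrices: list[FrequencyMatrix]) -> list[FrequencyMatrix]:
    """One matrix per TF class: the first by accession order."""
    chosen: dict[str, FrequencyMatrix] = {}
    for m in sorted(matrices, key=lambda m: m.matrix_id):
        chosen.setdefault(m.tf_class, m)
    return [m for m in matrices if chosen[m.tf_class] is m]


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the configured stages; see the module docstring.

    Raises a :class:`CiscompareError` subclass (with the failing stage in
    the log) on any stage error; the CLI maps that to a nonzero exit.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ciscompare",
        "version": __version__,
        "seed": config.seed,
        "cutoff_mode": config.cutoff_mode,
        "strands": config.strands,
        "level": config.level,
        "non_redundant": config.non_redundant,
    }
    hits: list[MotifHit] = []

    if config.presence_matrix is not None:
        logger.info("stage scan: skipped (presence matrix supplied)")
        presence = io.read_presence_tsv(config.presence_matrix, level=config.level)
        manifest["presence_matrix"] = str(config.presence_matrix)
    else:
        t0 = time.perf_counter()
        sequences = io.read_fasta(config.fasta)
        matrices = io.read_transfac(config.matrices, class_overrides=config.class_overrides)
        if config.non_redundant:
            matrices = _select_non_redundant(matrices)
        cutoffs = _resolve_cutoffs(config, matrices)
        manifest["matrices"] = [m.matrix_id for m in matrices]
        manifest["sequences"] = [s.sequence_id for s in sequences]
        manifest["cutoffs"] = cutoffs
        hits = scan_sequences(sequences, matrices, cutoffs, strands=config.strands)
        logger.info("stage scan: %d hits in %.2fs", len(hits), time.perf_counter() - t0)
        io.write_hits_tsv(hits, out / "hits.tsv")
        io.write_hits_bed(hits, out / "hits.bed")
        presence = build_presence_matrix(
            hits, level=config.level, column_ids=[s.sequence_id for s in sequences]
        )

    io.write_presence_tsv(presence, out / "presence_matrix.tsv")

    results: list[ContrastResult] = []
    report_lines: list[str] = []
    for contrast in config.contrasts:
        t0 = time.perf_counter()
        missing = (contrast.positive_ids | contrast.negative_ids) - set(presence.column_ids)
        if missing:
            raise ConfigError(
                f"contrast {contrast.name!r} references sequences absent from the "
                f"presence matrix: {sorted(missing)}"
            )
        common = common_sites(presence, contrast.positive_ids)
        diff = differential_sites(presence, contrast)
        results.append(ContrastResult(contrast.name, common, diff))
        logger.info("stage compare[%s]: %.2fs", contrast.name, time.perf_counter() - t0)
        report_lines += [
            f"contrast: {contrast.name}",
            f"  positives: {', '.join(sorted(contrast.positive_ids))}",
            f"  negatives: {', '.join(sorted(contrast.negative_ids)) or '(none)'}",
            f"  common sites ({len(common)}): {', '.join(sorted(common)) or '(none)'}",
            f"  differential sites ({len(diff)}): {', '.join(sorted(diff)) or '(none)'}",
            "",
        ]
    if config.contrasts:
        (out / "contrasts_report.txt").write_text("\n".join(report_lines))
        with open(out / "contrasts.tsv", "w") as fh:
            fh.write("contrast\tkind\tbinding_site\n")
            for r in results:
                for s in sorted(r.common):
                    fh.write(f"{r.name}\tcommon\t{s}\n")
                for s in sorted(r.differential):
                    fh.write(f"{r.name}\tdifferential\t{s}\n")

    manifest["contrasts"] = {
        r.name: {"common": sorted(r.common), "differential": sorted(r.differential)}
        for r in results
    }
    manifest["aggregation"] = "class-sum over all matrices sharing a tf_class"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(output_dir=out, presence=presence, hits=hits,
                     contrasts=results, manifest=manifest)
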