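"""Declarative pipeline configuration.

A single YAML file describes a full run: inputs (FASTA + TRANSFAC
matrices, or a precomputed presence matrix for a comparative-only run),
the cutoff mode, strand policy, aggregation level, named contrasts and
the output directory.  Example::

    fasta: sequences.fa
    matrices: matrices.dat
    cutoff:
      mode: fixed          # or minFN10 | minSum | minFP
      value: 0.85          # required for fixed
      # profiles: profiles.tsv   # required for the calibrated modes
    strands: both
    level: class
    non_redundant: false
    seed: 0
    contrasts:
      - name: sensory_vesicle
        positives: [1UP1.4, 4UP1.3, 2D0.8, 1CiHox3, mb1]
        negatives: [mb2, ma2, ma3, mb1RARE]
    output_dir: results
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .comparative import GroupContrast
from .exceptions import ConfigError

CUTOFF_MODES = ("fixed", "minFN10", "minSum", "minFP")


@dataclass
class PipelineConfig:
    output_dir: str
    fasta: Optional[str] = None
    matrices: Optional[str] = None
    presence_matrix: Optional[str] = None
    cutoff_mode: str = "fixed"
    cutoff_value: Optional[float] = None
    profiles: Optional[str] = None
    class_overrides: dict = field(default_factory=dict)
    strands: str = "both"
    level: str = "class"
    non_redundant: bool = False
    seed: int = 0
    contrasts: list[GroupContrast] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cutoff_mode not in CUTOFF_MODES:
            raise ConfigError(
                f"cutoff mode must be one of {CUTOFF_MODES}, got {self.cutoff_mode!r}"
            )
        if self.presence_matrix is None:
            if self.fasta is None or self.matrices is None:
                raise ConfigError(
                    "config needs either presence_matrix (comparative-only run) "
                    "or both fasta and matrices"
                )
            if self.cutoff_mode == "fixed":
                if self.cutoff_value is None or not 0.0 <= self.cutoff_value <= 1.0:
                    raise ConfigError("fixed cutoff mode needs a value in [0, 1]")
            elif self.profiles is None:
                raise ConfigError(
                    f"cutoff mode {self.cutoff_mode!r} needs a calibrated profiles file"
                )
        if self.strands not in ("+", "-", "both"):
            raise ConfigError(f"invalid strand policy {self.strands!r}")
        if self.level not in ("class", "consensus"):
            raise ConfigError(f"invalid analysis level {self.level!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cutoff = raw.pop("cutoff", {}) or {}
        contrasts = [
            GroupContrast(
                name=c.get("name", f"contrast{i}"),
                positive_ids=frozenset(c.get("positives", [])),
                negative_ids=frozenset(c.get("negatives", [])),
            )
            for i, c in enumerate(raw.pop("contrasts", []) or [], start=1)
        ]
        known = {
            "fasta", "matrices", "presence_matrix", "class_overrides", "strands",
            "level", "non_redundant", "seed", "output_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError(f"{path}: output_dir is required")
        return cls(
            cutoff_mode=cutoff.get("mode", "fixed"),
            cutoff_value=cutoff.get("value"),
            profiles=cutoff.get("profiles"),
            contrasts=contrasts,
            **raw,
        )
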