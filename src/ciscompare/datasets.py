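"""Packaged reference tables from the chordate Hox cis-element study.

Three small tables ship with the package:

* expression annotations of the positive regulatory fragments (which
  ascidian / vertebrate neural territories each drives expression in);
* the class-level hit-count table of the fragments active in the
  ascidian sensory vesicle, against the mouse fragments that are not;
* the Pbx/Meis-class hit-count table over the same fragments.

They are the worked examples for the comparative layer: curated
presence matrices whose common/differential site extraction can be
checked against published results without any proprietary matrix data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .comparative import ExpressionAnnotation
from .scanner import PresenceMatrix


def _data_path(name: str):
    return resources.files("ciscompare").joinpath("data", name)


def load_expression_annotations() -> list[ExpressionAnnotation]:
    """Territory annotations of the positive cis-elements (8 fragments)."""
    with resources.as_file(_data_path("table1_annotations.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ExpressionAnnotation(
            sequence_id=row.sequence_id,
            species=row.species,
            territories=frozenset(row.territories.split(",")),
        )
        for row in df.itertuples()
    ]


def _load_presence(name: str) -> PresenceMatrix:
    with resources.as_file(_data_path(name)) as path:
        table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "binding_site"
    return PresenceMatrix(level="class", table=table)


def load_sensory_vesicle_counts() -> PresenceMatrix:
    """4 TF classes x 9 sequences: fragments active in the sensory
    vesicle (first five columns) vs mouse fragments that are not."""
    return _load_presence("table2_sensory_vesicle_counts.tsv")


def load_pbx_meis_counts() -> PresenceMatrix:
    """6 Pbx/Meis TF classes x 10 sequences."""
    return _load_presence("table3_pbx_meis_counts.tsv")
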