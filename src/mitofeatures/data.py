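"""Packaged reference tables for the *S. teleckojensis* mitogenome.

Plain-text transcriptions of the published annotation (GenBank MF198253):
the gene organization table, the partitioned nucleotide composition table,
and the codon-usage table. They serve as inputs for reproduction checks
and as the template for the default synthetic genome layout.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation import FeatureTable, parse_feature_table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mitofeatures").joinpath("data", name)))


def reference_feature_table_path() -> Path:
    return _data_path("mf198253_features.tsv")


def load_reference_feature_table() -> FeatureTable:
    """The published 37-gene + CR organization table."""
    return parse_feature_table(reference_feature_table_path(), complete=True)


def load_reference_composition() -> pd.DataFrame:
    """Published partitioned composition (percent T/C/A/G, skews, sizes)."""
    return pd.read_csv(_data_path("mf198253_composition.tsv"), sep="\t")


def load_reference_codon_usage() -> pd.DataFrame:
    """Published per-codon counts and RSCU (total / J-strand / N-strand)."""
    return pd.read_csv(_data_path("mf198253_codon_usage.tsv"), sep="\t")


def reference_intergenic_column() -> list[int | None]:
    """The printed intergenic-nucleotides column (None for the first row)."""
    df = pd.read_csv(
        reference_feature_table_path(), sep="\t", dtype={"intergenic": "Int64"}
    )
    return [None if pd.isna(v) else int(v) for v in df["intergenic"]]
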