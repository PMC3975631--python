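"""TSV readers/writers and packaged study tables.

All tabular interchange is tab-separated text: count matrices have features
in rows (first column ``feature_id``) and samples in columns; metadata has a
``sample_id`` key column and a ``group`` column.  The package ships the
published study's printed clinical table and the three printed
significant-candidate lists as data files for reanalysis of the reported
summary numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    if counts.isna().any().any():
        raise ValueError(f"missing values in count matrix {path}")
    if (counts < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "group" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'group' column")
    return meta


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _data_path(name: str):
    return resources.files("srnasep.data").joinpath(name)


def load_study_cohort() -> pd.DataFrame:
    """The published study's clinical table (15 patients, 3 groups)."""
    with resources.as_file(_data_path("study_cohort.tsv")) as p:
        return read_metadata(p)


def load_reported_candidates() -> dict[str, list[str]]:
    """The published per-comparison significant small-RNA lists."""
    out = {}
    for name in ("lymphogen", "occult", "combined"):
        with resources.as_file(_data_path(f"reported_candidates_{name}.txt")) as p:
            out[name] = read_id_list(p)
    return out
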