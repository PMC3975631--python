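"""Descriptive cohort summaries of the clinical sample metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import round_half_up

NUMERIC_COLUMNS = ("age", "tumor_size_mm", "total_rna_ug", "rin")
CATEGORICAL_COLUMNS = ("pL", "pV", "pT", "rete_testis", "stage")


@dataclass
class CohortSummary:
    """Per-group numeric means/stdevs and categorical tallies.

    ``numeric`` carries full precision (group x (column, stat) with stats
    n/mean/stdev/min/max; stdev is the n-1 sample standard deviation, NaN for
    single-sample groups).  ``to_display`` applies 1-decimal
    half-away-from-zero rounding; rounding never feeds back into computation.
    """

    numeric: pd.DataFrame
    categorical: dict[str, pd.DataFrame]

    def to_display(self) -> pd.DataFrame:
        disp = self.numeric.copy()
        for col in disp.columns:
            if col[1] in ("mean", "stdev"):
                disp[col] = disp[col].map(
                    lambda v: np.nan if pd.isna(v) else round_half_up(v, 1)
                )
        return disp


def summarize_cohort(metadata: pd.DataFrame) -> CohortSummary:
    """Summarize clinical metadata per group.

    Numeric columns (age, tumour size, total RNA yield, RIN) get n, mean,
    n-1 stdev, min and max per group; categorical columns are tallied.
    Raises on non-numeric values in numeric columns.
    """
    if "group" not in metadata.columns:
        raise KeyError("metadata must have a 'group' column")
    present_numeric = [c for c in NUMERIC_COLUMNS if c in metadata.columns]
    for col in present_numeric:
        vals = pd.to_numeric(metadata[col], errors="coerce")
        bad = metadata.index[vals.isna() & metadata[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in column {col!r}: rows {list(bad)}")
    sizes = metadata.groupby("group", sort=False).size()
    if present_numeric:
        grouped = metadata.groupby("group", sort=False)[present_numeric]
        numeric = grouped.agg(["count", "mean", "std", "min", "max"])
        numeric.columns = pd.MultiIndex.from_tuples(
            [(c, {"count": "n", "std": "stdev"}.get(s, s)) for c, s in numeric.columns]
        )
    else:  # metadata may carry group labels only (e.g. synthetic designs)
        numeric = pd.DataFrame(index=sizes.index)
        numeric.columns = pd.MultiIndex.from_tuples([], names=(None, None))
    numeric.insert(0, ("samples", "n"), sizes)
    categorical = {
        col: metadata.groupby("group", sort=False)[col].value_counts().unstack(fill_value=0)
        for col in CATEGORICAL_COLUMNS
        if col in metadata.columns
    }
    return CohortSummary(numeric, categorical)
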