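"""Candidate small-RNA screening.

For each comparison (lymphogen, occult, or both metastasized subtypes
combined, always against the non-metastasized reference group) the screen:

1. normalizes raw counts to CPM (counts per million annotated small-RNA reads),
2. filters features to those with a group-mean raw count of at least 50 reads
   in one of the compared groups *and* at least a two-fold CPM difference
   between group means (pseudocount 0.5 on the means),
3. fits a univariate Firth logistic regression of group membership on
   log2(CPM + 1) per filtered feature, and
4. calls features with an (unadjusted) penalized-likelihood-ratio p <= alpha
   significant.

No multiple-testing adjustment is applied by default — the screen is
explicitly exploratory — but a Benjamini-Hochberg toggle is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .firth import fit_firth_logistic

REFERENCE_GROUP = "non_metastasized"
COMPARISON_TARGETS = ("lymphogen", "occult", "combined")

DEFAULT_MIN_READS = 50.0
DEFAULT_MIN_FOLD = 2.0
DEFAULT_ALPHA = 0.05
PSEUDOCOUNT = 0.5  # added to CPM group means for fold-change ratios


@dataclass(frozen=True)
class ComparisonSpec:
    """One of the study's three comparisons against the reference group."""

    target: str
    reference: str = REFERENCE_GROUP

    def __post_init__(self) -> None:
        if self.target not in COMPARISON_TARGETS:
            raise ValueError(
                f"target must be one of {COMPARISON_TARGETS}, got {self.target!r}"
            )

    def target_groups(self) -> tuple[str, ...]:
        if self.target == "combined":
            return ("lymphogen", "occult")
        return (self.target,)

    def split_samples(self, metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
        """(reference sample ids, target sample ids) from a metadata frame."""
        groups = metadata["group"]
        known = set(groups.unique())
        wanted = set(self.target_groups()) | {self.reference}
        unknown = wanted - known
        if unknown:
            raise KeyError(f"groups absent from metadata: {sorted(unknown)}")
        ref = list(groups.index[groups == self.reference])
        tgt = list(groups.index[groups.isin(self.target_groups())])
        return ref, tgt


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million over each sample's annotated small-RNA reads."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {list(zero.index)}")
    return counts / totals * 1e6


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for reported numbers)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _group_means(
    counts: pd.DataFrame, cpm: pd.DataFrame, ref: list[str], tgt: list[str]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean_ref_raw": counts[ref].mean(axis=1),
            "mean_target_raw": counts[tgt].mean(axis=1),
            "mean_ref_cpm": cpm[ref].mean(axis=1),
            "mean_target_cpm": cpm[tgt].mean(axis=1),
        }
    )


def candidate_filter(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: ComparisonSpec,
    min_reads: float = DEFAULT_MIN_READS,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> list[str]:
    """Features with >= ``min_reads`` mean raw reads in one compared group and
    a CPM group-mean ratio >= ``min_fold`` (or <= 1/min_fold), matrix order."""
    ref, tgt = comparison.split_samples(metadata)
    if min(len(ref), len(tgt)) < 2:
        raise ValueError("both compared groups need at least 2 samples")
    m = _group_means(counts, normalize_cpm(counts), ref, tgt)
    fc = (m["mean_target_cpm"] + PSEUDOCOUNT) / (m["mean_ref_cpm"] + PSEUDOCOUNT)
    enough_reads = (m["mean_ref_raw"] >= min_reads) | (m["mean_target_raw"] >= min_reads)
    folded = (fc >= min_fold) | (fc <= 1.0 / min_fold)
    return list(counts.index[enough_reads & folded])


@dataclass
class CandidateTable:
    """Screen output for one comparison (all features; filtered ones fitted)."""

    comparison: ComparisonSpec
    table: pd.DataFrame
    alpha: float
    min_reads: float
    min_fold: float
    adjust: str | None = None

    @property
    def candidate_list(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def filtered_ids(self) -> list[str]:
        return list(self.table.index[self.table["passed_filter"]])


def screen(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: ComparisonSpec,
    alpha: float = DEFAULT_ALPHA,
    min_reads: float = DEFAULT_MIN_READS,
    min_fold: float = DEFAULT_MIN_FOLD,
    adjust: str | None = None,
) -> CandidateTable:
    """Run the full candidate screen for one comparison.

    ``adjust`` may be ``None`` (raw p-values, the default) or ``"bh"``
    (Benjamini-Hochberg across the filtered features).  The reported
    ``fold_change`` is the expression ratio of CPM group means
    (target / reference, pseudocount 0.5); ``odds_ratio`` is the logistic
    odds ratio per log2-CPM unit with its 95% profile penalized-likelihood
    CI — two different quantities, both reported, neither conflated.
    """
    if adjust not in (None, "bh"):
        raise ValueError("adjust must be None or 'bh'")
    ref, tgt = comparison.split_samples(metadata)
    cpm = normalize_cpm(counts)
    m = _group_means(counts, cpm, ref, tgt)
    out = m[["mean_ref_cpm", "mean_target_cpm"]].copy()
    out["fold_change"] = (m["mean_target_cpm"] + PSEUDOCOUNT) / (
        m["mean_ref_cpm"] + PSEUDOCOUNT
    )
    filtered = candidate_filter(counts, metadata, comparison, min_reads, min_fold)
    out["passed_filter"] = out.index.isin(filtered)
    out["p_value"] = np.nan
    out["odds_ratio"] = np.nan
    out["ci_low"] = np.nan
    out["ci_high"] = np.nan

    x_mat = np.log2(cpm[ref + tgt] + 1.0)
    y = np.concatenate([np.zeros(len(ref)), np.ones(len(tgt))])
    for fid in filtered:
        fit = fit_firth_logistic(x_mat.loc[fid].to_numpy(), y)
        out.loc[fid, ["p_value", "odds_ratio", "ci_low", "ci_high"]] = (
            fit.p_value,
            fit.odds_ratio,
            fit.ci_low,
            fit.ci_high,
        )
    if adjust == "bh" and filtered:
        p_adj = multipletests(out.loc[filtered, "p_value"].to_numpy(), method="fdr_bh")[1]
        out["p_adjusted"] = np.nan
        out.loc[filtered, "p_adjusted"] = p_adj
        out["significant"] = out["passed_filter"] & (out["p_adjusted"] <= alpha)
    else:
        out["significant"] = out["passed_filter"] & (out["p_value"] <= alpha)
    return CandidateTable(comparison, out, alpha, min_reads, min_fold, adjust)


@dataclass
class OverlapStats:
    """Intersection structure of the three comparisons' candidate lists."""

    sizes: dict[str, int]
    pairwise: pd.DataFrame  # list_a, list_b, intersection, pct_of_b
    venn_regions: dict[str, int]  # keys like "100", "110", "111"


def overlap_stats(lists: dict[str, list[str]]) -> OverlapStats:
    """Pairwise intersections (|A∩B| and its percentage of |B|, rounded half
    away from zero) plus the 7 Venn region counts when 3 lists are given."""
    sets: dict[str, set[str]] = {}
    for name, ids in lists.items():
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in list {name!r}")
        sets[name] = set(ids)
    rows = []
    for a, b in ((a, b) for a in sets for b in sets if a != b):
        inter = len(sets[a] & sets[b])
        pct = round_half_up(100.0 * inter / len(sets[b])) if sets[b] else 0.0
        rows.append({"list_a": a, "list_b": b, "intersection": inter, "pct_of_b": pct})
    pairwise = pd.DataFrame(rows)
    venn: dict[str, int] = {}
    if len(sets) == 3:
        names = list(sets)
        for mask in range(1, 8):
            bits = tuple((mask >> (2 - i)) & 1 for i in range(3))
            inside = [s for s, bit in zip(names, bits) if bit]
            outside = [s for s, bit in zip(names, bits) if not bit]
            region = set.intersection(*(sets[s] for s in inside))
            for s in outside:
                region -= sets[s]
            venn["".join(map(str, bits))] = len(region)
    return OverlapStats({k: len(v) for k, v in sets.items()}, pairwise, venn)


def plot_venn(stats: OverlapStats, names: list[str], path: str) -> None:
    """Three-circle Venn sketch of the candidate-list overlaps (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = [(0.35, 0.6), (0.65, 0.6), (0.5, 0.35)]
    for (cx, cy), name in zip(centers, names):
        ax.add_patch(plt.Circle((cx, cy), 0.25, alpha=0.3))
        ax.text(cx, cy + 0.28, f"{name} (n={stats.sizes[name]})", ha="center")
    label_pos = {
        "100": (0.25, 0.65), "010": (0.75, 0.65), "001": (0.5, 0.22),
        "110": (0.5, 0.68), "101": (0.38, 0.45), "011": (0.62, 0.45),
        "111": (0.5, 0.53),
    }
    for bits, (x, y) in label_pos.items():
        ax.text(x, y, str(stats.venn_regions.get(bits, 0)), ha="center")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)
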