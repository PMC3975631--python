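"""Tag annotation against a small-RNA reference and count-matrix assembly.

A trimmed tag matches a reference entry when it equals the mature sequence,
is a prefix of it missing at most ``end_tolerance`` 3' bases, or extends it
by at most ``end_tolerance`` 3' bases (the extra bases are ignored).  miRNA
entries take priority over ncRNA entries when both classes match; a tag is
``unique`` when exactly one entry of the winning class matches, ``ambiguous``
when several do, ``unannotated`` otherwise.  Only uniquely assigned tags
enter the count matrix; ambiguous and unannotated tags are tallied in the
per-sample library statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import MIRNA, ReferenceLibrary
from .trim import TagTable, TrimCounts

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNANNOTATED = "unannotated"

DEFAULT_END_TOLERANCE = 2


@dataclass(frozen=True)
class Assignment:
    status: str  # unique | ambiguous | unannotated
    feature_id: str | None = None  # present iff unique


class TagAnnotator:
    """Prebuilt exact-lookup index over a reference for fast tag assignment."""

    def __init__(self, reference: ReferenceLibrary, end_tolerance: int = DEFAULT_END_TOLERANCE):
        if end_tolerance < 0:
            raise ValueError("end_tolerance must be >= 0")
        self.reference = reference
        self.end_tolerance = end_tolerance
        # full sequences and 3'-truncations (up to the tolerance) -> entries
        self._by_seq: dict[str, list] = {}
        for e in reference:
            for k in range(0, end_tolerance + 1):
                if len(e.sequence) - k < 1:
                    break
                key = e.sequence[: len(e.sequence) - k]
                self._by_seq.setdefault(key, []).append((e, k))

    def _matches(self, tag: str) -> list:
        found = {}
        # tag equals a sequence, or is a sequence truncated by <= tol bases
        for e, _k in self._by_seq.get(tag, []):
            found[e.feature_id] = e
        # tag extends a sequence by <= tol ignored 3' bases
        for k in range(1, self.end_tolerance + 1):
            if len(tag) - k < 1:
                break
            for e, trunc in self._by_seq.get(tag[: len(tag) - k], []):
                if trunc == 0 and len(e.sequence) == len(tag) - k:
                    found[e.feature_id] = e
        return list(found.values())

    def assign(self, tag: str) -> Assignment:
        matches = self._matches(tag)
        if not matches:
            return Assignment(UNANNOTATED)
        mirna_hits = [e for e in matches if e.rna_class == MIRNA]
        winning = mirna_hits if mirna_hits else matches
        if len(winning) == 1:
            return Assignment(UNIQUE, winning[0].feature_id)
        return Assignment(AMBIGUOUS)


def annotate_tag(
    tag: str, reference: ReferenceLibrary, end_tolerance: int = DEFAULT_END_TOLERANCE
) -> Assignment:
    """Assign one tag (convenience wrapper; builds the index each call)."""
    return TagAnnotator(reference, end_tolerance).assign(tag)


@dataclass
class LibraryStats:
    """Per-sample library accounting: reads through trimming and annotation."""

    total_reads: int
    reads_after_trim: int
    annotated_reads: int
    tags_total: int
    tags_annotated: int
    tags_ambiguous: int = 0

    @property
    def pct_after_trim(self) -> float:
        return 100.0 * self.reads_after_trim / self.total_reads if self.total_reads else 0.0

    @property
    def pct_annotated(self) -> float:
        return (
            100.0 * self.annotated_reads / self.reads_after_trim
            if self.reads_after_trim
            else 0.0
        )

    @property
    def pct_tags_annotated(self) -> float:
        return 100.0 * self.tags_annotated / self.tags_total if self.tags_total else 0.0


@dataclass
class CountData:
    """Raw count matrix (features x samples) with per-sample library stats."""

    counts: pd.DataFrame
    stats: dict[str, LibraryStats] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def build_count_matrix(
    samples: dict[str, tuple[TagTable, TrimCounts]],
    reference: ReferenceLibrary,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> CountData:
    """Assemble the feature x sample raw count matrix from per-sample tags.

    Rows are the reference feature ids in reference order; a cell is the total
    read count of tags uniquely assigned to that feature in that sample.
    Ambiguous/unannotated tags contribute nothing to the matrix but are
    tallied in each sample's :class:`LibraryStats`.
    """
    if not samples:
        raise ValueError("need at least one sample")
    sample_ids = list(samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    annotator = TagAnnotator(reference, end_tolerance)
    mat = pd.DataFrame(
        0, index=reference.feature_ids, columns=sample_ids, dtype=np.int64
    )
    stats: dict[str, LibraryStats] = {}
    for sid, (tags, acc) in samples.items():
        annotated_reads = 0
        tags_annotated = 0
        tags_ambiguous = 0
        col: dict[str, int] = {}
        for tag, n in tags.counts.items():
            a = annotator.assign(tag)
            if a.status == UNIQUE:
                col[a.feature_id] = col.get(a.feature_id, 0) + n
                annotated_reads += n
                tags_annotated += 1
            elif a.status == AMBIGUOUS:
                tags_ambiguous += 1
        if col:
            mat[sid] = pd.Series(col).reindex(mat.index, fill_value=0).astype(np.int64)
        stats[sid] = LibraryStats(
            total_reads=acc.total,
            reads_after_trim=acc.kept,
            annotated_reads=annotated_reads,
            tags_total=tags.n_tags,
            tags_annotated=tags_annotated,
            tags_ambiguous=tags_ambiguous,
        )
    return CountData(mat, stats)


_STAT_COLUMNS = [
    ("total_reads", lambda s: s.total_reads),
    ("reads_after_trim", lambda s: s.reads_after_trim),
    ("pct_after_trim", lambda s: s.pct_after_trim),
    ("annotated_reads", lambda s: s.annotated_reads),
    ("pct_annotated", lambda s: s.pct_annotated),
    ("tags_total", lambda s: s.tags_total),
    ("tags_annotated", lambda s: s.tags_annotated),
    ("pct_tags_annotated", lambda s: s.pct_tags_annotated),
]


def library_summary(
    data: CountData, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample library statistics plus per-group mean/stdev/min/max.

    ``metadata`` must map every sample (index) to a ``group``.  The stdev is
    the n-1 sample standard deviation and is reported as NaN for single-sample
    groups.  Returns ``(per_sample, per_group)`` frames; the per-group frame
    has one ``<column>_<stat>`` column per statistic in {mean, stdev, min, max}.
    """
    missing = [s for s in data.sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    rows = {
        sid: {name: fn(data.stats[sid]) for name, fn in _STAT_COLUMNS}
        for sid in data.sample_ids
    }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample.insert(0, "group", metadata.loc[per_sample.index, "group"])
    agg = per_sample.groupby("group", sort=False).agg(["mean", "std", "min", "max"])
    agg.columns = [f"{col}_{stat.replace('std', 'stdev')}" for col, stat in agg.columns]
    return per_sample, agg
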