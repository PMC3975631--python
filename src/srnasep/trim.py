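"""Adapter trimming and tag collapsing for small-RNA reads.

A read is kept when a 3' adapter is located: either the full adapter occurs
inside the read, or a prefix of the adapter (at least ``min_overlap`` bases,
at most ``max_mismatch`` mismatches) runs through the read's 3' end.  The
insert is everything before the leftmost such match.  Reads with no adapter
are discarded (``no_adapter``); kept inserts shorter than ``min_length``
(default 15 nt) are discarded (``too_short``).  Kept inserts are collapsed
into a tag table: unique insert sequence -> read count.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DEFAULT_MIN_LENGTH = 15
DEFAULT_MIN_OVERLAP = 7
DEFAULT_MAX_MISMATCH = 1

KEPT = "kept"
NO_ADAPTER = "no_adapter"
TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TrimResult:
    status: str  # kept | no_adapter | too_short
    insert: str | None = None  # present iff kept


@dataclass
class TrimCounts:
    """Per-sample trimming account; kept + no_adapter + too_short = total."""

    kept: int = 0
    no_adapter: int = 0
    too_short: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.no_adapter + self.too_short


@dataclass
class TagTable:
    """Collapsed kept inserts of one sample: tag sequence -> read count."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, tag: str, n: int = 1) -> None:
        self.counts[tag] = self.counts.get(tag, 0) + n

    @property
    def n_tags(self) -> int:
        return len(self.counts)

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())


def _find_adapter(
    read: str, adapter: str, min_overlap: int, max_mismatch: int
) -> int | None:
    """Leftmost start of an adapter match, or None.

    A match at position i aligns adapter[:k] with read[i:i+k] where
    k = min(len(adapter), len(read) - i); requires k >= min_overlap and at
    most max_mismatch mismatches.
    """
    la, lr = len(adapter), len(read)
    # fast path: exact full-adapter occurrence bounds the search
    exact = read.find(adapter)
    stop = exact if exact >= 0 else lr - min_overlap
    for i in range(0, stop + 1):
        k = min(la, lr - i)
        if k < min_overlap:
            break
        mm = 0
        for a, b in zip(adapter, read[i : i + k]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return i
    return exact if exact >= 0 else None


def trim_read(
    read: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> TrimResult:
    """Trim one read; see module docstring for the matching rule."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1 or len(adapter) < min_overlap:
        raise ValueError("require adapter length >= min_overlap >= 1")
    pos = _find_adapter(read.upper(), adapter.upper(), min_overlap, max_mismatch)
    if pos is None:
        return TrimResult(NO_ADAPTER)
    if pos < min_length:
        return TrimResult(TOO_SHORT)
    return TrimResult(KEPT, read[:pos].upper())


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterable[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file.

    Malformed records abort with the index of the offending record.
    """
    with _open_maybe_gzip(path) as handle:
        it = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index} in {path}: {exc}") from exc
            yield str(rec.seq)
            index += 1


def trim_reads(
    reads: Iterable[str],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[TagTable, TrimCounts]:
    """Trim an iterable of read sequences and collapse kept inserts to tags."""
    tags = TagTable()
    acc = TrimCounts()
    for read in reads:
        res = trim_read(read, adapter, min_overlap, max_mismatch, min_length)
        if res.status == KEPT:
            acc.kept += 1
            tags.add(res.insert)
        elif res.status == NO_ADAPTER:
            acc.no_adapter += 1
        else:
            acc.too_short += 1
    return tags, acc


def trim_readset(
    fastq: str | Path,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[TagTable, TrimCounts]:
    """Trim every record of a FASTQ file; returns (TagTable, TrimCounts)."""
    return trim_reads(iter_fastq(fastq), adapter, min_overlap, max_mismatch, min_length)
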