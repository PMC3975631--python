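"""Small-RNA reference libraries (mature miRNA + ncRNA sequences).

A :class:`ReferenceLibrary` is the annotation universe the quantifier matches
trimmed tags against: short mature-miRNA entries (miRBase-style ids) and longer
non-coding RNA entries (ENST-style ids).  Real analyses load it from FASTA;
:func:`generate_reference` builds a synthetic one with the same shape so the
whole pipeline is testable without downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

MIRNA = "mirna"
NCRNA = "ncrna"

#: Tags sharing this prefix length with two distinct entries would be ambiguous
#: under the default 3'-end tolerance; the generator keeps prefixes unique.
_UNIQUE_PREFIX = 13

MIRNA_LENGTHS = (18, 25)
NCRNA_LENGTHS = (30, 120)


@dataclass(frozen=True)
class RefEntry:
    """One reference sequence: id, class (mirna/ncrna) and mature sequence."""

    feature_id: str
    rna_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.rna_class not in (MIRNA, NCRNA):
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if not self.sequence:
            raise ValueError(f"{self.feature_id}: empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            raise ValueError(f"{self.feature_id}: sequence has non-ACGT characters")


@dataclass
class ReferenceLibrary:
    """Ordered collection of unique reference entries."""

    entries: list[RefEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in reference")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RefEntry]:
        return iter(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def by_id(self, feature_id: str) -> RefEntry:
        try:
            return self._index[feature_id]
        except AttributeError:
            self._index = {e.feature_id: e for e in self.entries}
            return self._index[feature_id]

    def to_fasta(self, path: str | Path | io.TextIOBase) -> None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.feature_id, description=e.rna_class)
            for e in self.entries
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "ReferenceLibrary":
        """Load from FASTA.

        The RNA class is taken from the description field when present
        (``mirna``/``ncrna``); otherwise inferred from the id (ENST-prefixed
        ids are ncRNA, everything else miRNA — the miRBase/ensembl convention).
        """
        entries = []
        for rec in SeqIO.parse(path, "fasta"):
            desc = rec.description.split(maxsplit=1)
            cls_word = desc[1].strip().lower() if len(desc) > 1 else ""
            if cls_word in (MIRNA, NCRNA):
                rna_class = cls_word
            else:
                rna_class = NCRNA if rec.id.startswith("ENST") else MIRNA
            entries.append(RefEntry(rec.id, rna_class, str(rec.seq).upper()))
        return cls(entries)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_reference(n_mirna: int, n_ncrna: int, seed: int) -> ReferenceLibrary:
    """Generate a synthetic reference library.

    miRNA entries get miRBase-style ids (``mir-sim-<k>``) and lengths 18-25 nt;
    ncRNA entries get ENST-style ids and lengths 30-120 nt.  Sequences are
    unique and additionally no two entries share their first 13 bases, so a
    trimmed tag can prefix-match at most one entry even under 3'-end jitter.

    Deterministic for a fixed ``seed``.
    """
    if n_mirna < 0 or n_ncrna < 0:
        raise ValueError("entry counts must be non-negative")
    if n_mirna + n_ncrna < 1:
        raise ValueError("reference must contain at least one entry")
    rng = np.random.default_rng(seed)
    entries: list[RefEntry] = []
    prefixes: set[str] = set()

    def draw(length_range: tuple[int, int]) -> str:
        while True:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = _random_sequence(rng, length)
            if seq[:_UNIQUE_PREFIX] not in prefixes:
                prefixes.add(seq[:_UNIQUE_PREFIX])
                return seq

    for k in range(n_mirna):
        entries.append(RefEntry(f"mir-sim-{k + 1}", MIRNA, draw(MIRNA_LENGTHS)))
    for k in range(n_ncrna):
        ncrna_id = f"ENST{90000000000 + k:011d}"
        entries.append(RefEntry(ncrna_id, NCRNA, draw(NCRNA_LENGTHS)))
    return ReferenceLibrary(entries)
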