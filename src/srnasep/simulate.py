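"""Synthetic blood small-RNA data with known truth.

Emulates the study design the pipeline targets: three groups
(non-metastasized reference, lymphogen-metastasized, occult-metastasized),
five samples each, negative-binomial small-RNA counts with a log-normal
baseline across features, and raw base-space reads consisting of a mature
small-RNA insert (with optional 3'-end jitter) followed by a 3' adapter,
diluted with the read classes a trimmer must reject or fail to annotate:
adapter-free junk reads, short-insert reads (<15 nt) and reads whose insert
is not in the reference.

Default noise fractions (junk 0.25, short 0.02, unannotated 0.13 of total
reads) put ~73% of reads past trimming and ~82% of trimmed reads into the
annotated class, matching the accounting structure of real blood small-RNA
libraries at desk scale; absolute 10^7 read depth is not emulated.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import TagAnnotator, UNANNOTATED
from .reference import ReferenceLibrary, generate_reference
from .trim import NO_ADAPTER, trim_read

GROUPS = ("non_metastasized", "lymphogen", "occult")
REFERENCE_GROUP = "non_metastasized"

#: Illumina-style small-RNA 3' adapter; chosen for negligible self-overlap
#: similarity so adapter location in simulated reads is unambiguous.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthImplant:
    """One implanted effect: feature expression multiplied by ``fold_change``
    in every listed group (other groups keep the baseline).

    ``baseline_mean`` optionally pins the feature's expected raw count in the
    unaffected groups (at the mean library size); real discriminating blood
    miRNAs are moderately-to-highly expressed, whereas a random log-normal
    baseline draw would sometimes place an implant below any detectable level.
    """

    feature_id: str
    groups: tuple[str, ...]
    fold_change: float
    baseline_mean: float | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.baseline_mean is not None and self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


@dataclass
class TruthSet:
    """Ground truth echoed by the simulator.

    ``expected_pairs`` lists feature pairs expected to jointly give complete
    linear separation: pairs of implants that hit the same groups with at
    least a four-fold effect (a heuristic expectation, verified empirically
    by the tests rather than guaranteed).
    """

    implants: list[TruthImplant] = field(default_factory=list)
    expected_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return [t.feature_id for t in self.implants]


@dataclass
class SimulationConfig:
    n_per_group: int = 5
    groups: tuple[str, ...] = GROUPS
    n_features: int = 200
    mirna_fraction: float = 0.7
    library_size_mean: float = 1e5
    library_size_cv: float = 0.25
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.8
    dispersion: float = 0.2
    truth_set: tuple[TruthImplant, ...] = ()
    adapter: str = DEFAULT_ADAPTER
    junk_read_fraction: float = 0.25
    short_fragment_fraction: float = 0.02
    unannotated_tag_fraction: float = 0.13
    end_jitter: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in (
            "junk_read_fraction",
            "short_fragment_fraction",
            "unannotated_tag_fraction",
            "mirna_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.library_size_cv < 0 or self.dispersion < 0:
            raise ValueError("library_size_cv and dispersion must be >= 0")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.n_per_group)]

    def group_of(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g in self.groups for i in range(self.n_per_group)}

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["truth_set"] = [asdict(t) for t in self.truth_set]
        d["groups"] = list(self.groups)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["groups"] = tuple(d.get("groups", GROUPS))
        d["truth_set"] = tuple(
            TruthImplant(t["feature_id"], tuple(t["groups"]), t["fold_change"])
            for t in d.get("truth_set", [])
        )
        return cls(**d)


def metadata_frame(config: SimulationConfig) -> pd.DataFrame:
    """Minimal sample metadata (sample_id index, group column)."""
    ids = config.sample_ids()
    return pd.DataFrame({"group": [config.group_of()[s] for s in ids]}, index=pd.Index(ids, name="sample_id"))


def _expected_pairs(implants: tuple[TruthImplant, ...]) -> list[tuple[str, str]]:
    strong = [
        t
        for t in implants
        if max(t.fold_change, 1.0 / t.fold_change) >= 4.0
    ]
    pairs = []
    for i, a in enumerate(strong):
        for b in strong[i + 1 :]:
            if set(a.groups) == set(b.groups):
                pairs.append(tuple(sorted((a.feature_id, b.feature_id))))
    return pairs


def simulate_counts(
    config: SimulationConfig, reference: ReferenceLibrary
) -> tuple[pd.DataFrame, TruthSet]:
    """Draw the feature x sample raw count matrix.

    Per-feature relative abundances come from a log-normal baseline; implanted
    truth features have their abundance multiplied by the implant fold change
    in affected groups; abundances are renormalized per group and scaled by a
    per-sample library size (gamma-distributed with the configured CV), then
    counts are negative-binomial with the configured overdispersion
    (variance mu + dispersion * mu^2; dispersion 0 means Poisson).
    """
    ref_ids = reference.feature_ids
    id_to_row = {f: i for i, f in enumerate(ref_ids)}
    for t in config.truth_set:
        if t.feature_id not in id_to_row:
            raise KeyError(f"truth feature {t.feature_id!r} not in reference")
        for g in t.groups:
            if g not in config.groups:
                raise ValueError(f"unknown group {g!r} in truth_set")
    rng = np.random.default_rng(config.seed)
    n_feat = len(ref_ids)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_feat)

    # pin implants with a requested baseline mean to that expected raw count
    # (as a proportion of the mean library size), rescaling the free features
    pinned = {
        id_to_row[t.feature_id]: t.baseline_mean / config.library_size_mean
        for t in config.truth_set
        if t.baseline_mean is not None
    }
    if pinned:
        p_fixed = sum(pinned.values())
        if p_fixed >= 1.0:
            raise ValueError("pinned truth baselines exceed the library size")
        free = np.ones(n_feat, dtype=bool)
        free[list(pinned)] = False
        scale = (1.0 - p_fixed) / baseline[free].sum()
        baseline = baseline * scale
        for row, p in pinned.items():
            baseline[row] = p

    fold = np.ones((n_feat, len(config.groups)))
    for t in config.truth_set:
        for g in t.groups:
            fold[id_to_row[t.feature_id], config.groups.index(g)] = t.fold_change

    sample_ids = config.sample_ids()
    if config.library_size_cv == 0:
        lib = np.full(len(sample_ids), config.library_size_mean)
    else:
        shape = 1.0 / config.library_size_cv**2
        lib = rng.gamma(shape, config.library_size_mean / shape, len(sample_ids))

    counts = np.empty((n_feat, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        g_idx = config.groups.index(config.group_of()[sid])
        w = baseline * fold[:, g_idx]
        mu = lib[j] * w / w.sum()
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_nb = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    matrix = pd.DataFrame(counts, index=pd.Index(ref_ids, name="feature_id"), columns=sample_ids)
    truth = TruthSet(list(config.truth_set), _expected_pairs(config.truth_set))
    return matrix, truth


def _random_seqs(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[str]:
    lengths = rng.integers(lo, hi + 1, size=n)
    return ["".join(_BASES[rng.integers(0, 4, size=k)]) for k in lengths]


def _jittered_insert(seq: str, rng: np.random.Generator, jitter: int) -> str:
    if jitter == 0:
        return seq
    off = int(rng.integers(-jitter, jitter + 1))
    if off < 0:
        return seq[:off]
    if off > 0:
        return seq + "".join(_BASES[rng.integers(0, 4, size=off)])
    return seq


def simulate_reads(
    counts: pd.DataFrame,
    reference: ReferenceLibrary,
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit one gzipped FASTQ per sample from a simulated count matrix.

    Each counted feature contributes ``count`` reads of its mature sequence
    (with 3'-end jitter up to ``end_jitter`` nt) followed by the adapter.
    Junk (adapter-free), short-insert and unannotated-insert reads are added
    so they make up the configured fractions of each sample's total; the
    remaining fraction is the annotatable feature reads.  Deterministic for a
    fixed config seed (gzip headers carry no timestamp).
    """
    for f in counts.index:
        reference.by_id(f)  # KeyError if a counted feature is missing
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    annotator = TagAnnotator(reference, end_tolerance=config.end_jitter)
    j, s, u = (
        config.junk_read_fraction,
        config.short_fragment_fraction,
        config.unannotated_tag_fraction,
    )
    denom = 1.0 - j - s - u
    paths: dict[str, Path] = {}
    for sid in counts.columns:
        col = counts[sid]
        n_feature_reads = int(col.sum())
        if denom > 0:
            total = int(round(n_feature_reads / denom))
        else:
            # degenerate config: noise crowds out feature reads entirely
            total = n_feature_reads
            n_feature_reads = 0
        n_junk = int(round(j * total))
        n_short = int(round(s * total))
        n_unann = int(round(u * total))

        reads: list[str] = []
        if n_feature_reads:
            for fid, c in col.items():
                if c == 0:
                    continue
                seq = reference.by_id(fid).sequence
                for _ in range(int(c)):
                    reads.append(_jittered_insert(seq, rng, config.end_jitter) + config.adapter)
        for insert in _random_seqs(rng, n_short, 5, 14):
            reads.append(insert + config.adapter)
        k = 0
        while k < n_unann:
            insert = _random_seqs(rng, 1, 18, 25)[0]
            if annotator.assign(insert).status != UNANNOTATED:
                continue
            read = insert + config.adapter
            if trim_read(read, config.adapter).insert != insert:
                continue
            reads.append(read)
            k += 1
        k = 0
        while k < n_junk:
            read = _random_seqs(rng, 1, 35, 50)[0]
            if trim_read(read, config.adapter).status != NO_ADAPTER:
                continue
            reads.append(read)
            k += 1

        order = rng.permutation(len(reads))
        path = out_dir / f"{sid}.fastq.gz"
        raw = open(path, "wb")
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            with io.TextIOWrapper(gz, encoding="ascii") as fh:
                for idx, r in enumerate(order):
                    read = reads[r]
                    fh.write(f"@{sid}:{idx}\n{read}\n+\n{'I' * len(read)}\n")
        raw.close()
        paths[sid] = path
    return paths


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ReferenceLibrary, pd.DataFrame, TruthSet, pd.DataFrame]:
    """Reference + counts + truth + metadata in one call (no read files)."""
    n_mirna = int(round(config.n_features * config.mirna_fraction))
    n_ncrna = config.n_features - n_mirna
    reference = generate_reference(n_mirna, n_ncrna, seed=config.seed)
    counts, truth = simulate_counts(config, reference)
    return reference, counts, truth, metadata_frame(config)
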