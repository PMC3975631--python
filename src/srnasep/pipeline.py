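"""Top-level pipeline: process -> screen (3 comparisons) -> pairs -> report.

Everything is driven by a :class:`PipelineConfig` (loadable from YAML) and
produces a flat bundle of TSV tables plus two JSON files (summary and a
manifest of parameters/versions).  Outputs contain no timestamps, so runs
with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import CountData, build_count_matrix, library_summary
from .cohort import summarize_cohort
from .io import read_counts, read_metadata, write_counts
from .pairs import enumerate_separating_pairs
from .reference import ReferenceLibrary
from .screen import (
    ComparisonSpec,
    normalize_cpm,
    overlap_stats,
    screen,
)
from .trim import trim_readset

COMPARISONS = ("lymphogen", "occult", "combined")


@dataclass
class PipelineConfig:
    metadata: str
    out_dir: str
    counts: str | None = None  # precomputed count matrix TSV ...
    fastq_dir: str | None = None  # ... or raw reads + reference
    reference: str | None = None
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_length: int = 15
    min_overlap: int = 7
    max_mismatch: int = 1
    end_tolerance: int = 2
    alpha: float = 0.05
    min_reads: float = 50.0
    min_fold: float = 2.0
    adjust: str | None = None
    pool: str = "significant"  # feature pool for the pair search
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counts is None and (self.fastq_dir is None or self.reference is None):
            raise ValueError(
                "config must name either 'counts' or both 'fastq_dir' and 'reference'"
            )
        if self.pool not in ("significant", "filtered"):
            raise ValueError("pool must be 'significant' or 'filtered'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        missing = [k for k in ("metadata", "out_dir") if k not in d]
        if missing:
            raise ValueError(f"config missing required inputs: {missing}")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _process_stage(config: PipelineConfig, out: Path) -> CountData:
    reference = ReferenceLibrary.from_fasta(config.reference)
    fastqs = sorted(
        p
        for p in Path(config.fastq_dir).iterdir()
        if p.name.endswith((".fastq", ".fastq.gz", ".fq", ".fq.gz"))
    )
    if not fastqs:
        raise FileNotFoundError(f"no FASTQ files in {config.fastq_dir}")
    samples = {}
    for fq in fastqs:
        sid = fq.name
        for suffix in (".gz", ".fastq", ".fq"):
            sid = sid.removesuffix(suffix)
        samples[sid] = trim_readset(
            fq,
            config.adapter,
            min_overlap=config.min_overlap,
            max_mismatch=config.max_mismatch,
            min_length=config.min_length,
        )
    return build_count_matrix(samples, reference, end_tolerance=config.end_tolerance)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = read_metadata(config.metadata)
    summary: dict = {"comparisons": {}}

    stage = "process"
    try:
        if config.counts is not None:
            data = CountData(read_counts(config.counts))
        else:
            data = _process_stage(config, out)
        write_counts(data.counts, out / "counts.tsv")
        if data.stats:
            per_sample, per_group = library_summary(data, metadata)
            per_sample.rename_axis("sample_id").to_csv(out / "library_stats.tsv", sep="\t")
            per_group.rename_axis("group").to_csv(out / "library_stats_by_group.tsv", sep="\t")

        stage = "cohort"
        cohort = summarize_cohort(metadata.loc[data.sample_ids])
        cohort.to_display().to_csv(out / "cohort_summary.tsv", sep="\t")

        stage = "screen"
        tables = {}
        for target in COMPARISONS:
            tab = screen(
                data.counts,
                metadata,
                ComparisonSpec(target),
                alpha=config.alpha,
                min_reads=config.min_reads,
                min_fold=config.min_fold,
                adjust=config.adjust,
            )
            tab.table.rename_axis("feature_id").to_csv(
                out / f"candidates_{target}.tsv", sep="\t"
            )
            tables[target] = tab
            summary["comparisons"][target] = {
                "n_filtered": len(tab.filtered_ids),
                "n_significant": len(tab.candidate_list),
            }
        ov = overlap_stats({t: tables[t].candidate_list for t in COMPARISONS})
        ov.pairwise.to_csv(out / "overlap.tsv", sep="\t", index=False)
        summary["overlap"] = {
            "sizes": ov.sizes,
            "venn_regions": ov.venn_regions,
            "pairwise": ov.pairwise.to_dict(orient="records"),
        }

        stage = "pairs"
        log_cpm = np.log2(normalize_cpm(data.counts) + 1.0)
        for target in COMPARISONS:
            pool_ids = (
                tables[target].candidate_list
                if config.pool == "significant"
                else tables[target].filtered_ids
            )
            if len(pool_ids) < 2:
                summary["comparisons"][target]["n_separating_pairs"] = 0
                summary["comparisons"][target]["n_pairs_evaluated"] = 0
                continue
            pt = enumerate_separating_pairs(
                log_cpm, pool_ids, metadata, ComparisonSpec(target), pool=config.pool
            )
            pt.records.to_csv(out / f"pairs_{target}.tsv", sep="\t", index=False)
            summary["comparisons"][target]["n_separating_pairs"] = pt.n_separating
            summary["comparisons"][target]["n_pairs_evaluated"] = len(pt.records)
            summary["comparisons"][target]["svm_disagreements"] = pt.svm_disagreements
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["pool"] = config.pool
    _json_dump(summary, out / "summary.json")

    manifest = {
        "srnasep_version": __version__,
        "parameters": asdict(config),
        "inputs": {},
    }
    for key in ("metadata", "counts", "reference"):
        path = getattr(config, key)
        if path is not None:
            manifest["inputs"][key] = _sha256(Path(path))
    if config.fastq_dir is not None:
        manifest["inputs"]["fastq"] = {
            p.name: _sha256(p) for p in sorted(Path(config.fastq_dir).iterdir())
        }
    _json_dump(manifest, out / "manifest.json")
    return summary
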