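import numpy as np
import pytest

from srnasep.annotate import TagAnnotator, UNIQUE
from srnasep.reference import generate_reference
from srnasep.simulate import (
    SimulationConfig,
    TruthImplant,
    metadata_frame,
    simulate_counts,
    simulate_dataset,
    simulate_reads,
)
from srnasep.trim import KEPT, iter_fastq, trim_read

MET_GROUPS = ("lymphogen", "occult")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_per_group=1)
    with pytest.raises(ValueError):
        SimulationConfig(junk_read_fraction=1.2)
    with pytest.raises(ValueError):
        TruthImplant("f", MET_GROUPS, fold_change=0.0)


def test_empty_truth_set_yields_no_truth_features():
    ref = generate_reference(10, 0, seed=1)
    _, truth = simulate_counts(SimulationConfig(n_features=10, seed=1), ref)
    assert truth.implants == [] and truth.expected_pairs == []


def test_counts_deterministic_for_fixed_seed():
    cfg = SimulationConfig(n_features=40, seed=9)
    ref = generate_reference(30, 10, seed=9)
    c1, _ = simulate_counts(cfg, ref)
    c2, _ = simulate_counts(cfg, ref)
    assert c1.equals(c2)


def test_unknown_truth_feature_rejected():
    ref = generate_reference(5, 0, seed=2)
    cfg = SimulationConfig(
        n_features=5, truth_set=(TruthImplant("missing", MET_GROUPS, 2.0),), seed=2
    )
    with pytest.raises(KeyError):
        simulate_counts(cfg, ref)


def test_matrix_shape_and_dtypes():
    cfg = SimulationConfig(n_features=25, n_per_group=3, seed=4)
    ref = generate_reference(20, 5, seed=4)
    counts, _ = simulate_counts(cfg, ref)
    assert counts.shape == (25, 9)
    assert (counts >= 0).all().all()
    assert counts.to_numpy().dtype.kind == "i"
    assert list(counts.index) == ref.feature_ids


def test_column_sums_track_library_size_at_zero_cv():
    """With library-size CV 0 and no overdispersion the generator targets the
    configured library size almost exactly (Poisson noise only).  With
    overdispersion the per-feature biological noise propagates into the sums
    — by design — so there the check is on the across-sample average."""
    cfg = SimulationConfig(
        n_features=150, library_size_mean=5e4, library_size_cv=0.0,
        dispersion=0.0, seed=6,
    )
    ref = generate_reference(100, 50, seed=6)
    counts, _ = simulate_counts(cfg, ref)
    rel_err = np.abs(counts.sum(axis=0) / 5e4 - 1.0)
    assert (rel_err < 0.10).all()
    assert rel_err.max() < 0.02  # essentially exact without overdispersion

    cfg_od = SimulationConfig(
        n_features=150, library_size_mean=5e4, library_size_cv=0.0, seed=6
    )
    counts_od, _ = simulate_counts(cfg_od, ref)
    assert abs(counts_od.sum(axis=0).mean() / 5e4 - 1.0) < 0.10


def test_implanted_fold_change_recovered_at_large_n():
    """Law-of-large-numbers check: 4-fold implant, 50 samples per group,
    pinned baseline mean 200 -> empirical group-mean ratio in [3.2, 4.8]."""
    cfg = SimulationConfig(
        n_per_group=50,
        n_features=100,
        seed=13,
        truth_set=(TruthImplant("mir-sim-3", MET_GROUPS, 4.0, baseline_mean=200),),
    )
    ref = generate_reference(70, 30, seed=13)
    counts, truth = simulate_counts(cfg, ref)
    assert truth.feature_ids == ["mir-sim-3"]
    meta = metadata_frame(cfg)
    g = meta["group"]
    ref_mean = counts.loc["mir-sim-3", g[g == "non_metastasized"].index].mean()
    for target in MET_GROUPS:
        tgt_mean = counts.loc["mir-sim-3", g[g == target].index].mean()
        assert 3.2 <= tgt_mean / ref_mean <= 4.8
    assert 150 <= ref_mean <= 250  # pinned baseline honoured


def test_expected_pairs_require_matching_groups_and_strong_fold():
    implants = (
        TruthImplant("a", MET_GROUPS, 6.0),
        TruthImplant("b", MET_GROUPS, 1 / 6),
        TruthImplant("c", ("lymphogen",), 8.0),
        TruthImplant("d", MET_GROUPS, 1.5),
    )
    ref = generate_reference(4, 0, seed=1)
    cfg = SimulationConfig(
        n_features=4,
        truth_set=tuple(
            TruthImplant(f"mir-sim-{i+1}", t.groups, t.fold_change)
            for i, t in enumerate(implants)
        ),
        seed=1,
    )
    _, truth = simulate_counts(cfg, ref)
    assert truth.expected_pairs == [("mir-sim-1", "mir-sim-2")]


def test_reads_single_feature_exact_record_count(tmp_path):
    cfg = SimulationConfig(
        n_features=1,
        junk_read_fraction=0,
        short_fragment_fraction=0,
        unannotated_tag_fraction=0,
        end_jitter=0,
        seed=3,
    )
    ref = generate_reference(1, 0, seed=3)
    counts, _ = simulate_counts(cfg, ref)
    counts.iloc[:, :] = 0
    counts.iloc[0, 0] = 10
    paths = simulate_reads(counts, ref, cfg, tmp_path)
    reads = list(iter_fastq(paths[counts.columns[0]]))
    assert len(reads) == 10
    assert all(r == ref.entries[0].sequence + cfg.adapter for r in reads)


def test_noise_free_reads_all_kept_and_annotatable(tmp_path):
    cfg = SimulationConfig(
        n_features=10,
        library_size_mean=400,
        junk_read_fraction=0,
        short_fragment_fraction=0,
        unannotated_tag_fraction=0,
        seed=8,
    )
    ref, counts, _, _ = simulate_dataset(cfg)
    paths = simulate_reads(counts, ref, cfg, tmp_path)
    ann = TagAnnotator(ref, end_tolerance=cfg.end_jitter)
    sid = counts.columns[0]
    for read in iter_fastq(paths[sid]):
        res = trim_read(read, cfg.adapter)
        assert res.status == KEPT
        assert ann.assign(res.insert).status == UNIQUE


def test_all_junk_leaves_nothing_after_trimming(tmp_path):
    cfg = SimulationConfig(
        n_features=5,
        library_size_mean=100,
        junk_read_fraction=1.0,
        short_fragment_fraction=0.0,
        unannotated_tag_fraction=0.0,
        seed=2,
    )
    ref, counts, _, _ = simulate_dataset(cfg)
    paths = simulate_reads(counts, ref, cfg, tmp_path)
    sid = counts.columns[0]
    statuses = {trim_read(r, cfg.adapter).status for r in iter_fastq(paths[sid])}
    assert statuses == {"no_adapter"}


def test_read_files_deterministic_bytewise(tmp_path):
    cfg = SimulationConfig(n_features=10, library_size_mean=300, seed=21)
    ref, counts, _, _ = simulate_dataset(cfg)
    p1 = simulate_reads(counts, ref, cfg, tmp_path / "a")
    p2 = simulate_reads(counts, ref, cfg, tmp_path / "b")
    sid = counts.columns[0]
    assert p1[sid].read_bytes() == p2[sid].read_bytes()


def test_trimming_survival_matches_noise_fractions(tmp_path):
    """Kept fraction ~ 1 - junk - short: within 1.5 points of 73% on a
    20000-read sample at the default noise settings."""
    cfg = SimulationConfig(
        n_features=150, library_size_mean=12000, seed=17
    )  # defaults: junk .25, short .02 -> expect ~73% kept
    ref, counts, _, _ = simulate_dataset(cfg)
    sid = counts.columns[0]
    paths = simulate_reads(counts[[sid]], ref, cfg, tmp_path)
    statuses = [trim_read(r, cfg.adapter).status for r in iter_fastq(paths[sid])]
    n = len(statuses)
    assert n > 15000
    kept_pct = 100.0 * sum(s == KEPT for s in statuses) / n
    assert abs(kept_pct - 73.0) <= 1.5
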