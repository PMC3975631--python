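import numpy as np
import pandas as pd
import pytest

from srnasep.pairs import (
    enumerate_separating_pairs,
    separable_bruteforce_2d,
    separable_exact_2d,
    separable_svm,
)
from srnasep.screen import ComparisonSpec, normalize_cpm
from srnasep.simulate import SimulationConfig, TruthImplant, simulate_dataset

from conftest import toy_metadata

XOR = (np.array([[0, 0], [1, 1], [0, 1], [1, 0.0]]), np.array([0, 0, 1, 1]))


def test_xor_is_not_separable():
    xy, lab = XOR
    assert not separable_exact_2d(xy, lab)
    assert not separable_svm(xy, lab)
    assert not separable_bruteforce_2d(xy, lab)


def test_shifted_clouds_are_separable():
    rng = np.random.default_rng(3)
    xy = rng.normal(0, 1, (12, 2))
    lab = np.array([0] * 6 + [1] * 6)
    xy[lab == 1, 0] += 10
    assert separable_exact_2d(xy, lab)
    assert separable_svm(xy, lab)
    assert separable_bruteforce_2d(xy, lab)


def test_boundary_point_breaks_strict_separation():
    # one class-1 point sits exactly on the class-0 hull edge
    xy = np.array([[0, 0], [2, 0], [1, 0], [3, 1.0]])
    lab = np.array([0, 0, 1, 1])
    assert not separable_exact_2d(xy, lab, strict=True)
    assert not separable_bruteforce_2d(xy, lab)


def test_shared_point_weakly_but_not_strictly_separable():
    xy = np.array([[0, 0], [1, 0], [1, 0], [2, 0.0]])
    lab = np.array([0, 0, 1, 1])
    assert not separable_exact_2d(xy, lab, strict=True)
    assert separable_exact_2d(xy, lab, strict=False)


def test_identical_points_mixed_labels():
    xy = np.zeros((4, 2))
    lab = np.array([0, 0, 1, 1])
    assert not separable_exact_2d(xy, lab)
    assert not separable_svm(xy, lab)


def test_degenerate_one_class_rejected():
    with pytest.raises(ValueError):
        separable_exact_2d(np.zeros((3, 2)), np.zeros(3))


def test_cross_oracle_agreement_on_random_instances():
    """Exact hull test, brute-force line enumeration and the SVM surrogate
    agree on 120 random 15-point instances (ties and collinearity forced on
    a quarter of them)."""
    rng = np.random.default_rng(42)
    for _ in range(120):
        k = int(rng.integers(2, 14))
        lab = np.array([0] * k + [1] * (15 - k))
        d = rng.uniform(0, 4)
        xy = rng.normal(0, 1, (15, 2))
        xy[lab == 1, 0] += d
        if rng.random() < 0.25:
            xy = np.round(xy * 2) / 2
        e = separable_exact_2d(xy, lab)
        assert e == separable_bruteforce_2d(xy, lab)
        assert e == separable_svm(xy, lab)


def test_invariance_under_permutation_and_axis_swap():
    rng = np.random.default_rng(7)
    for _ in range(25):
        k = int(rng.integers(2, 14))
        lab = np.array([0] * k + [1] * (15 - k))
        xy = rng.normal(0, 1, (15, 2))
        xy[lab == 1] += rng.uniform(0, 3)
        e = separable_exact_2d(xy, lab)
        perm = rng.permutation(15)
        assert separable_exact_2d(xy[perm], lab[perm]) == e
        assert separable_exact_2d(xy[:, ::-1], lab) == e


def _log_cpm(rows: dict[str, list[float]], meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(rows, index=meta.index).T


def test_complementary_pair_found_exactly():
    """Neither marker separates alone; their 2-D combination does."""
    meta = toy_metadata(5)
    ref = [s for s in meta.index if meta.loc[s, "group"] == "non_metastasized"]
    tgt = [s for s in meta.index if s not in ref]
    a = {s: v for s, v in zip(ref, [0, 1, 2, 3, 4])}
    a.update({s: v for s, v in zip(tgt, [0.5, 1.5, 2.5, 3.5, 4.5, 0.7, 1.7, 2.7, 3.7, 4.7])})
    b = {s: 4 - a[s] for s in ref}
    b.update({s: 5.2 - a[s] for s in tgt})  # a+b = 4 vs 5.2: pair separates
    c = {s: 1.0 for s in meta.index}  # constant: never separates
    mat = pd.DataFrame({"A": a, "B": b, "C": c}).T
    table = enumerate_separating_pairs(
        mat, ["A", "B", "C"], meta, ComparisonSpec("combined"), cross_check=True
    )
    assert len(table.records) == 3
    assert table.separating_pairs == [("A", "B")]
    assert table.svm_disagreements == 0
    # 1-D marginals overlap, so no pair involving the constant feature works
    assert not separable_exact_2d(
        np.column_stack([list(a.values()), list(c.values())]),
        np.array([0] * 5 + [1] * 10),
    )


def test_single_separating_feature_makes_all_its_pairs_separate():
    meta = toy_metadata(5)
    rng = np.random.default_rng(10)
    strong = np.concatenate([np.zeros(5), np.ones(10) * 8])
    mat = pd.DataFrame(
        {
            "strong": strong,
            "n1": rng.normal(0, 1, 15),
            "n2": rng.normal(0, 1, 15),
            "n3": rng.normal(0, 1, 15),
        },
        index=meta.index,
    ).T
    table = enumerate_separating_pairs(
        mat, ["strong", "n1", "n2", "n3"], meta, ComparisonSpec("combined")
    )
    assert len(table.records) == 6  # C(4,2)
    with_strong = {p for p in table.separating_pairs if "strong" in p}
    assert len(with_strong) == 3


def test_constant_matrix_has_no_separating_pairs():
    meta = toy_metadata(5)
    mat = pd.DataFrame(1.0, index=["A", "B", "C"], columns=meta.index)
    table = enumerate_separating_pairs(mat, ["A", "B", "C"], meta, ComparisonSpec("occult"))
    assert table.n_separating == 0


def test_pair_table_hygiene():
    meta = toy_metadata(5)
    mat = pd.DataFrame(1.0, index=["A", "B"], columns=meta.index)
    with pytest.raises(ValueError):
        enumerate_separating_pairs(mat, ["A"], meta, ComparisonSpec("occult"))
    with pytest.raises(KeyError):
        enumerate_separating_pairs(mat, ["A", "missing"], meta, ComparisonSpec("occult"))
    tab = enumerate_separating_pairs(mat, ["B", "A"], meta, ComparisonSpec("occult"))
    assert list(tab.records["small_rna_1"]) == ["A"]  # lexicographic, each pair once


def test_combined_separation_restricts_to_subtypes():
    """A pair separating all 10 metastasized samples from the 5 reference
    samples also separates each 5-sample subtype (subset property)."""
    cfg = SimulationConfig(
        n_features=60,
        dispersion=0.1,
        seed=99,
        truth_set=(
            TruthImplant("mir-sim-1", ("lymphogen", "occult"), 6.0, baseline_mean=400),
            TruthImplant("mir-sim-4", ("lymphogen", "occult"), 1 / 6, baseline_mean=400),
        ),
    )
    _, counts, _, meta = simulate_dataset(cfg)
    log_cpm = np.log2(normalize_cpm(counts) + 1.0)
    ids = ["mir-sim-1", "mir-sim-4", "mir-sim-7", "mir-sim-9"]
    tables = {
        t: enumerate_separating_pairs(log_cpm, ids, meta, ComparisonSpec(t))
        for t in ("combined", "lymphogen", "occult")
    }
    combined = set(tables["combined"].separating_pairs)
    assert combined  # the implanted pair separates
    assert combined <= set(tables["lymphogen"].separating_pairs)
    assert combined <= set(tables["occult"].separating_pairs)
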