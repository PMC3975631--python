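import pandas as pd
import pytest

from srnasep.io import write_counts
from srnasep.reference import RefEntry, ReferenceLibrary
from srnasep.simulate import (
    SimulationConfig,
    TruthImplant,
    simulate_dataset,
    simulate_reads,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: implanted discriminating markers of the shared end-to-end dataset
E2E_IMPLANTED = ("mir-sim-3", "mir-sim-8")


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """Simulated FASTQ dataset with an implanted separating marker pair."""
    root = tmp_path_factory.mktemp("e2e")
    cfg = SimulationConfig(
        n_features=80,
        library_size_mean=6000,
        dispersion=0.1,
        seed=42,
        truth_set=(
            TruthImplant(E2E_IMPLANTED[0], ("lymphogen", "occult"), 8.0, baseline_mean=400),
            TruthImplant(E2E_IMPLANTED[1], ("lymphogen", "occult"), 1 / 8, baseline_mean=400),
        ),
    )
    reference, counts, truth, metadata = simulate_dataset(cfg)
    reference.to_fasta(root / "reference.fasta")
    metadata.to_csv(root / "metadata.tsv", sep="\t")
    write_counts(counts, root / "sim_counts.tsv")
    simulate_reads(counts, reference, cfg, root / "reads")
    return {"root": root, "config": cfg, "counts": counts, "truth": truth}


@pytest.fixture(scope="session")
def adapter() -> str:
    return ADAPTER


@pytest.fixture()
def tiny_reference() -> ReferenceLibrary:
    """Hand-built 4-entry reference with known prefix structure."""
    return ReferenceLibrary(
        [
            RefEntry("mir-a", "mirna", "ACGTACGTACGTACGTACGT"),  # 20 nt
            RefEntry("mir-b", "mirna", "TTTTCCCCGGGGAAAATTTTCC"),  # 22 nt
            RefEntry("ENST00000000001", "ncrna", "ACGTACGTACGTACGTACGTCCCCCCCCCC"),  # extends mir-a
            RefEntry("ENST00000000002", "ncrna", "GATTACAGATTACAGATTACAGATTACAGA"),
        ]
    )


def toy_metadata(n_per_group: int = 5) -> pd.DataFrame:
    groups = ["non_metastasized", "lymphogen", "occult"]
    ids = [f"{g}_{i+1}" for g in groups for i in range(n_per_group)]
    return pd.DataFrame(
        {"group": [g for g in groups for _ in range(n_per_group)]},
        index=pd.Index(ids, name="sample_id"),
    )


@pytest.fixture()
def metadata15() -> pd.DataFrame:
    return toy_metadata(5)


def balanced_counts(rows: dict[str, list[int]], metadata: pd.DataFrame) -> pd.DataFrame:
    """Counts frame plus a filler feature equalizing library sizes, so CPM
    ratios equal raw ratios and hand arithmetic stays transparent."""
    df = pd.DataFrame(rows, index=metadata.index).T
    filler = df.sum(axis=0).max() * 2 - df.sum(axis=0)
    df.loc["filler"] = filler
    df.index.name = "feature_id"
    return df
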