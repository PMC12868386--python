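import numpy as np
import pandas as pd
import pytest

from fecaldiet.data_io import DatasetBundle


def _dates(*days):
    return pd.to_datetime(list(days))


@pytest.fixture
def tiny_bundle() -> DatasetBundle:
    """Two samples, two individuals (mother + infant), three taxa, triplicate
    reads — small enough to verify every number by hand."""
    taxa = pd.DataFrame({
        "taxon_id": ["Ficus", "Strelitzia", "Zea"],
        "rank": ["genus", "genus", "genus"],
        "genus_or_higher_label": ["Ficus", "Strelitzia", "Zea"],
        "marker": ["plant", "plant", "plant"],
        "provenance_score": [0.0, 0.0, 1.0],
    })
    samples = pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "individual_id": ["mom", "kid"],
        "group": ["A", "A"],
        "sex": ["F", "M"],
        "age_class": ["adult", "juvenile"],
        "mother_id": [np.nan, "mom"],
        "date": _dates("2023-09-01", "2023-09-02"),
    })
    rows = []
    for s in ("S1", "S2"):
        for rep in (1, 2, 3):
            rows += [(s, rep, "plant", "Ficus", 60),
                     (s, rep, "plant", "Strelitzia", 30),
                     (s, rep, "plant", "Zea", 10)]
    reads = pd.DataFrame(rows, columns=["sample_id", "replicate", "marker",
                                        "taxon_id", "reads"])
    obs = pd.DataFrame({
        "individual_id": ["mom", "mom", "kid"],
        "date": _dates("2023-09-01", "2023-09-03", "2023-09-02"),
        "taxon_id": ["Ficus", "Strelitzia", "Ficus"],
        "seconds": [120, 60, 90],
        "food_class": ["natural", "natural", "natural"],
    })
    return DatasetBundle(reads=reads, taxa=taxa, samples=samples, observations=obs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230815)


def random_read_table(rng, n_samples=5, n_taxa=8, n_reps=3, max_reads=40,
                      zero_prob=0.45):
    """A random long-format replicate read table for oracle-equivalence
    tests, with plenty of zeros to exercise every filter branch."""
    rows = []
    for s in range(n_samples):
        for rep in range(1, n_reps + 1):
            for t in range(n_taxa):
                if rng.random() < zero_prob:
                    continue
                rows.append((f"S{s}", rep, "plant" if t % 4 else "vertebrate",
                             f"T{t}", int(rng.integers(1, max_reads))))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "marker",
                                       "taxon_id", "reads"])
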