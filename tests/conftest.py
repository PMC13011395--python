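import numpy as np
import pandas as pd
import pytest

from virome_ap import synthetic_data as sd
from virome_ap.profiling import AbundanceMatrix, VOTUCatalog


@pytest.fixture(scope="session")
def small_cfg() -> sd.SyntheticConfig:
    return sd.SyntheticConfig(
        seed=7, n_votus=120, n_ap=30, n_hc=30, n_bacteria=20, sparsity=0.2,
        reads_per_sample=5_000,
    )


@pytest.fixture(scope="session")
def small_catalog(small_cfg) -> VOTUCatalog:
    return sd.generate_catalog(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_catalog):
    return sd.generate_cohort(small_cfg, small_catalog)


def make_catalog(lengths: dict[str, int], **extra) -> VOTUCatalog:
    """Tiny hand-built catalog for unit tests."""
    ids = list(lengths)
    df = pd.DataFrame(
        {
            "genome_length": [lengths[v] for v in ids],
            "family": extra.get("family", ["unassigned"] * len(ids)),
            "lifestyle": extra.get("lifestyle", ["unknown"] * len(ids)),
            "completeness": extra.get("completeness", [90.0] * len(ids)),
            "host_genus": extra.get("host_genus", [None] * len(ids)),
            "host_family": extra.get("host_family", [None] * len(ids)),
            "ko_set": extra.get("ko_set", [frozenset()] * len(ids)),
        },
        index=pd.Index(ids, name="votu_id"),
    )
    return VOTUCatalog(df)


def make_alignments(rows) -> pd.DataFrame:
    """rows: (sample, read, votu, start, end, score) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "read_id", "votu_id", "start", "end", "score"]
    )


def make_matrix(values, sample_ids=None, feature_ids=None, level="votu") -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(values.shape[1])]
    return AbundanceMatrix(sample_ids, feature_ids, values, level=level)
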