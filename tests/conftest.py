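import numpy as np
import pandas as pd
import pytest

from dsslong.cohort_io import CohortMetadata, FeatureTable, TaxonomyMap
from dsslong.synthetic_cohort import CohortConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared by read-only tests."""
    return generate(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    cfg = CohortConfig(
        seed=3, n_null=10, n_induced=2, n_depleted=3, n_bleeding=1,
        n_neutrophil=1, depth_log_mean=float(np.log(4.0e4)), depth_log_sd=0.2,
    )
    return generate(cfg)


@pytest.fixture
def tiny_table():
    counts = np.array([[5, 0, 3], [2, 2, 6], [1, 1, 1]])
    return FeatureTable(["s1", "s2", "s3"], ["fA", "fB", "fC"], counts)


@pytest.fixture
def tiny_taxonomy():
    return TaxonomyMap({
        "fA": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
               "Lactobacillaceae", "Lactobacillus", None),
        "fB": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
               "Lactobacillaceae", "Lactobacillus", None),
        "fC": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
               "Enterobacteriales", "Enterobacteriaceae", None, None),
    })


@pytest.fixture
def grid_metadata():
    rows = []
    for dose in (0, 1):
        for day in (0, 2, 4):
            for m in range(2):
                rows.append((f"d{dose}t{day}m{m}", dose, day, f"M{m}"))
    df = pd.DataFrame(rows, columns=["sample_id", "dose", "day", "mouse"])
    return CohortMetadata(df.set_index("sample_id"))
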