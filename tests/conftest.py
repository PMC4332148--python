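import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from proteoplex.catalog import default_catalog


@pytest.fixture(scope="session")
def catalog_and_defs():
    return default_catalog()


@pytest.fixture(scope="session")
def catalog(catalog_and_defs):
    return catalog_and_defs[0]


@pytest.fixture(scope="session")
def defs_by_name(catalog_and_defs):
    return {d.name: d for d in catalog_and_defs[1]}


def make_peptide_table(rows):
    """Build a peptide table from (sample, protein, peptide, area[, sn, std])."""
    records = []
    for row in rows:
        sample, protein, peptide, area = row[:4]
        sn = row[4] if len(row) > 4 else area / 100.0
        std = row[5] if len(row) > 5 else False
        records.append(
            {
                "sample_id": sample,
                "protein": protein,
                "peptide_id": peptide,
                "xic_area": float(area),
                "sn_ratio": float(sn),
                "is_standard": bool(std),
            }
        )
    return pd.DataFrame(records)


@pytest.fixture
def peptide_table_factory():
    return make_peptide_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
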