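from pathlib import Path

import pytest
from hypothesis import settings

from mirsnpkit import io

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).resolve().parents[1] / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def cohorts() -> dict:
    return {c.label: c for c in io.read_genotype_table(DATA / "cohort_genotype_counts.tsv")}


@pytest.fixture(scope="session")
def women_carriers() -> dict:
    return io.read_carrier_table(DATA / "cfhr5_women_carriers.tsv")


@pytest.fixture(scope="session")
def published_sites():
    return io.read_published_sites(DATA / "predicted_target_sites.tsv")


@pytest.fixture(scope="session")
def rflp_fixture():
    from mirsnpkit import make_rflp_fixture

    return make_rflp_fixture(seed=11)
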