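"""Shared fixtures: small synthetic cohorts and their transformed CDMs."""

from pathlib import Path

import pandas as pd
import pytest

from mimic2omop import (GeneratorConfig, VocabularyStore, generate_source,
                        run_etl)

DATA = Path(__file__).parent / "data"

#: light event rates for unit tests; marginal structure is unchanged
SMALL = dict(mean_labs_per_admission=30.0, mean_drugs_per_admission=8.0,
             mean_chart_events_per_admission=25.0)


@pytest.fixture(scope="session")
def vocab() -> VocabularyStore:
    return VocabularyStore.fixture()


@pytest.fixture(scope="session")
def small_source():
    return generate_source(GeneratorConfig(n_patients=40, seed=7, **SMALL))


@pytest.fixture(scope="session")
def small_result(small_source):
    return run_etl(small_source)


@pytest.fixture(scope="session")
def acceptance_source():
    """The seed-fixed 500-patient cohort at the default study conditions."""
    return generate_source(GeneratorConfig(n_patients=500, seed=42))


@pytest.fixture(scope="session")
def acceptance_result(acceptance_source):
    return run_etl(acceptance_source)


@pytest.fixture(scope="session")
def saps2_oracle() -> pd.DataFrame:
    return pd.read_csv(DATA / "saps2_oracle.csv")


@pytest.fixture(scope="session")
def derived_oracle() -> pd.DataFrame:
    return pd.read_csv(DATA / "derived_oracle.csv")


@pytest.fixture(scope="session")
def alignment_manifest() -> pd.DataFrame:
    return pd.read_csv(DATA / "alignment_manifest.csv", dtype="object")
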