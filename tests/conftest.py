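import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cuegene.physiology import PhenotypeRecord, compute_fluxes
from cuegene.synthetic import StudyConfig, generate_study


def phenotype_records(phenotypes: pd.DataFrame) -> list[PhenotypeRecord]:
    return [
        PhenotypeRecord(r.sample_id, r.B0_mg, r.Bt_mg, r.t_days, r.delta_co2_ppm)
        for r in phenotypes.itertuples()
    ]


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (Poisson counts, seed 0)."""
    return generate_study(StudyConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    """Fully deterministic study: sigma1 = sigma2 = 0, rounded counts."""
    return generate_study(StudyConfig(seed=7, sigma1=0.0, sigma2=0.0, count_noise="none"))


@pytest.fixture(scope="session")
def default_fluxes(default_study):
    records = compute_fluxes(phenotype_records(default_study.phenotypes))
    return {f.sample_id: f for f in records}
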