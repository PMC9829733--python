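import numpy as np
import pandas as pd
import pytest

from vgm.synthetic import (
    TruthParams,
    WorldConfig,
    gen_banding_records,
    gen_world,
)


@pytest.fixture(scope="session")
def small_world():
    """6 species x 4 years on a coarse grid: fast shared world."""
    return gen_world(WorldConfig(n_species=6, n_years=4, seed=42))


@pytest.fixture(scope="session")
def model_level_records(small_world):
    records, truth = gen_banding_records(
        small_world, TruthParams(), n_per_species_year=25, mode="model_level", seed=7
    )
    return records, truth


@pytest.fixture(scope="session")
def spatial_records(small_world):
    records, truth = gen_banding_records(
        small_world, TruthParams(), n_per_species_year=15, mode="spatial", seed=8
    )
    return records, truth


@pytest.fixture(scope="session")
def fitted_single(model_level_records):
    """One moderately sized single-driver fit shared across tests."""
    from vgm.model import ModelSpec, build_inputs, fit

    records, truth = model_level_records
    spec = ModelSpec(chains=2, warmup=600, draws=800, seed=11)
    inputs = build_inputs(records, spec)
    result = fit(spec, inputs, check_convergence=False)
    return result, truth


@pytest.fixture
def toy_records():
    """Small hand-built record table passing all validators."""
    n = 10
    return pd.DataFrame(
        {
            "record_id": [f"R{i}" for i in range(n)],
            "species_code": ["SP000"] * 5 + ["SP001"] * 5,
            "date": pd.to_datetime(["2001-09-15"] * n),
            "lon": np.linspace(-100, -90, n),
            "lat": np.linspace(30, 45, n),
            "precision_km": 0.0,
            "age_class": "adult",
            "record_type": "banding",
            "banding_code": 3,
        }
    )
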