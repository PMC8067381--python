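from dataclasses import replace

import numpy as np
import pytest

from herdbudget import (
    CowRecord,
    EconomicInputs,
    HerdConfig,
    generate_herd,
)

#: 20,000 cows total (10,000 per treatment arm), farm mix preserved.
CALIBRATION_FARMS = (9895, 2842, 7263)
CALIBRATION_SEED = 42


def make_cow(
    cow_id: str = "c1",
    services: tuple[float, ...] = (),
    conception: float | None = None,
    treatment: str = "PGOD",
    farm: str = "2",
    cbsi: int = 71,
    follow_up: float = 84.0,
) -> CowRecord:
    """Minimal hand-built cow record for metric tests."""
    return CowRecord(
        cow_id=cow_id,
        freeze_brand=2,
        farm=farm,
        treatment=treatment,
        parity_class="1",
        bcs_class="ge2.75",
        cbsi_days=cbsi,
        service_days=services,
        conception_day=conception,
        censor_day=None if conception is not None else follow_up,
    )


@pytest.fixture(scope="session")
def calibration_herd():
    """One large synthetic herd (~10,000 cows per arm) shared by the
    calibration-recovery tests."""
    config = HerdConfig(n_per_farm=CALIBRATION_FARMS, seed=CALIBRATION_SEED)
    records = generate_herd(config)
    return config, records


@pytest.fixture()
def default_inputs() -> EconomicInputs:
    return EconomicInputs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210406)
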