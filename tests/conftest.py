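import numpy as np
import pytest

import vesselmass as vm


@pytest.fixture(scope="session")
def strategy_table():
    return vm.load_strategy_table()


@pytest.fixture(scope="session")
def bundle():
    return vm.load_published_bundle()


@pytest.fixture(scope="session")
def noisy_fleet():
    """One default synthetic fleet (sigma_log=0.2, seed 3) with estimated masses."""
    cfg = vm.default_fleet_config(sigma_log=0.2)
    records = vm.generate_fleet(cfg, seed=3)
    masses, methods = vm.estimate_fleet(records)
    return records, masses, methods


@pytest.fixture(scope="session")
def noisy_fit(noisy_fleet):
    records, masses, _ = noisy_fleet
    return vm.fit_loglog(records, masses_kg=masses)


def make_powerlaw_records(
    vtype: vm.VesselType,
    slope: float,
    intercept: float,
    n: int = 30,
    sigma: float = 0.0,
    seed: int = 0,
    loa_range=(5.0, 100.0),
):
    """Records drawn exactly from mass = exp(intercept) * LOA^slope * noise."""
    rng = np.random.default_rng(seed)
    loa = np.exp(rng.uniform(np.log(loa_range[0]), np.log(loa_range[1]), size=n))
    eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    mass = np.exp(intercept) * loa**slope * np.exp(eps)
    return [
        vm.VesselRecord(
            record_id=f"{vtype.value}-{i}",
            vessel_type=vtype,
            loa_m=float(loa[i]),
            displacement_kg=float(mass[i]),
            source="online",
        )
        for i in range(n)
    ]
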