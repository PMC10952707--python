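import numpy as np
import pandas as pd
import pytest

from agespec.io_formats import BetaMatrix
from agespec.synthetic import SimulationConfig, simulate_cohorts


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down study: 4,000 probes, full donor counts, 8 DMR blocks."""
    defaults = dict(n_probes=4000, n_dmr_blocks=8, seed=11)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """(beta, sheet, manifest, truth) for the shared small simulation."""
    return simulate_cohorts(sim_config)


@pytest.fixture()
def toy_beta() -> BetaMatrix:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(5, 4)),
        index=[f"p{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )
    return BetaMatrix(data)


def paired_sheet(n_infant=3, n_adolescent=3) -> pd.DataFrame:
    rows = []
    for cohort, prefix, n in (("infant", "I", n_infant), ("adolescent", "A", n_adolescent)):
        for i in range(n):
            donor = f"{prefix}{i + 1:02d}"
            for condition in ("quiescent", "activated"):
                rows.append(
                    {
                        "sample_id": f"{donor}_{condition}",
                        "donor_id": donor,
                        "cohort": cohort,
                        "condition": condition,
                        "batch": cohort,
                        "sex": "F" if i % 2 else "M",
                    }
                )
    return pd.DataFrame(rows)
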