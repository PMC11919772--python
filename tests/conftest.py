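import numpy as np
import pytest

from methvar import sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(n_cohorts=2, n_cases=40, n_controls=40, n_probes=300,
                         fraction_vmp_up=0.05, fraction_vmp_down=0.05,
                         fraction_dmp=0.05, variance_ratio=3.0,
                         mean_shift=0.8, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    beta, detp, intensity, sheet, truth = sim.generate_cohort(small_config, 0)
    return {"beta": beta, "detp": detp, "intensity": intensity,
            "samplesheet": sheet, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
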