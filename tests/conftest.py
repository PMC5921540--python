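import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ampcna as a

settings.register_profile(
    "ampcna",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ampcna")


@pytest.fixture
def tiny_coverage() -> pd.DataFrame:
    """4 amplicons (2 genes) x 3 samples, hand-sized raw coverages."""
    return pd.DataFrame(
        {
            "s1": [100.0, 120.0, 80.0, 200.0],
            "s2": [210.0, 260.0, 190.0, 400.0],
            "s3": [95.0, 110.0, 85.0, 210.0],
        },
        index=["ERBB2_1", "ERBB2_2", "FGFR1_1", "FGFR1_2"],
    )


@pytest.fixture(scope="session")
def spiked_cohort():
    """Simulated 48-gene cohort with strong gains and losses spiked at 5%."""
    cfg = a.SimulationConfig(seed=42)
    rng = np.random.default_rng(7)
    spikes = a.choose_spikes(cfg, fraction=0.05, clonal_cn=8.0, rng=rng)
    # convert a third of the spiked genes to deep losses
    spikes = [
        (g, s, 0.2 if int(g[1:]) % 3 == 0 else c) for (g, s, c) in spikes
    ]
    cfg.spiked_cnas = spikes
    cov, truth = a.simulate_cohort(cfg)
    return cov, truth


@pytest.fixture(scope="session")
def spiked_results(spiked_cohort):
    cov, _ = spiked_cohort
    return a.CopyNumberModel(cov).fit()
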