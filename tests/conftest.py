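import numpy as np
import pandas as pd
import pytest

from cfmeth.core import SampleMethylome
from cfmeth.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across tests (read-only)."""
    cfg = SimConfig(seed=42, n_islands=120, n_e_genes=8, n_m_genes=4)
    samples, truth, _ = simulate_cohort(cfg)
    return cfg, samples, truth


def make_sample(sample_id, group, rows, chrom="chrS"):
    """Build a SampleMethylome from (pos, n_meth, n_total) triples."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [r[0] for r in rows],
            "n_meth": [r[1] for r in rows],
            "n_total": [r[2] for r in rows],
        }
    )
    return SampleMethylome(sample_id, group, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
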