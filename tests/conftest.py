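import numpy as np
import pandas as pd
import pytest

from melres import (
    GeneSignature,
    SimulationConfig,
    simulate_cell_line_panel,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """18-line noiseless-ish panel with a 3-probe planted support."""
    cfg = SimulationConfig(n_probes=40, n_lines=18, support_size=3,
                           effect_scale=1.0, noise_sd=0.3, seed=11)
    return simulate_cell_line_panel(cfg)


@pytest.fixture
def planted_cohort():
    """200-patient cohort with a 5-probe planted hazard signal."""
    cfg = SimulationConfig(n_probes=40, n_patients=200, support_size=5,
                           effect_scale=0.4, seed=7)
    rng = np.random.default_rng(99)
    w = np.zeros(40)
    idx = rng.choice(40, 5, replace=False)
    w[idx] = 0.4 * (-1.0) ** np.arange(5)
    return simulate_cohort(cfg, w, label="planted"), w


@pytest.fixture
def planted_signature(planted_cohort):
    cohort, w = planted_cohort
    probes = cohort.expression.index[np.flatnonzero(w)]
    return GeneSignature(pd.DataFrame({"probe_id": probes, "weight": w[w != 0]}))


def make_null_cohort(n_patients=150, n_probes=30, seed=0):
    cfg = SimulationConfig(n_probes=n_probes, n_patients=n_patients,
                           support_size=0, seed=seed)
    return simulate_cohort(cfg, np.zeros(n_probes), null_mode=True, label="null")
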