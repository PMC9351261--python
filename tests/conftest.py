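import numpy as np
import pytest

from ungated.panel import default_panel
from ungated.synthetic import (CohortConfig, default_channel_models,
                               derive_latent, generate_cohort,
                               generate_events_for_individual)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """20 individuals x 4,000 events, default (mixed-signal) scenario."""
    config = CohortConfig(n_individuals=20, n_events_per_individual=4000, seed=42)
    tables, outcomes, truth = generate_cohort(config)
    return config, tables, outcomes, truth


@pytest.fixture(scope="session")
def clean_events(panel):
    """One individual, no debris/doublets/dead/outliers/drift: pure mixtures."""
    config = CohortConfig(
        n_individuals=2, n_events_per_individual=30_000, seed=7,
        debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        outlier_rate=0.0, drift_amplitude=0.0)
    latent = derive_latent("S0001", 0.0, default_channel_models(panel))
    rng = np.random.default_rng(123)
    return latent, generate_events_for_individual(latent, config, rng)
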