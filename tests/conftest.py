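import numpy as np
import pandas as pd
import pytest

from metabogen import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Two-stratum cohort small enough for fast unit tests."""
    cfg = simulate.CohortConfig(
        n_individuals=500, n_strata=2, n_blocks=3, block_size=10, ld_decay=0.8, seed=11
    )
    return simulate.generate_genotypes(cfg)


@pytest.fixture(scope="session")
def default_panel_spec():
    return simulate.TraitPanelSpec.default(seed=5)


@pytest.fixture(scope="session")
def planted_panel(small_cohort, default_panel_spec):
    rng = np.random.default_rng(7)
    effects = [
        simulate.make_planted_effect(mode, default_panel_spec, vid, rng)
        for mode, vid in zip(simulate.PLEIOTROPY_MODES, [f"var{i:05d}" for i in range(5)])
    ]
    return simulate.generate_trait_panel(small_cohort, default_panel_spec, effects, seed=13)


@pytest.fixture()
def toy_instruments():
    return pd.DataFrame(
        {
            "beta_exposure": [0.1, 0.2, 0.3],
            "se_exposure": [0.01, 0.01, 0.01],
            "beta_outcome": [0.03, 0.06, 0.09],
            "se_outcome": [0.02, 0.03, 0.05],
        }
    )
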