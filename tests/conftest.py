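import numpy as np
import pytest

from sporegerm import (
    EnsembleConfig,
    GammaSpec,
    FIG3_SCAN_VALUES,
    get_preset,
    gr_copy_scan,
    run_ensemble,
)

# The single fixed seed used by every stochastic reproduction test.
TEST_SEED = 0


@pytest.fixture(scope="session")
def fig1():
    return get_preset("fig1")


@pytest.fixture(scope="session")
def fig2c():
    return get_preset("fig2c")


@pytest.fixture(scope="session")
def fig2d():
    return get_preset("fig2d")


@pytest.fixture(scope="session")
def fig3():
    return get_preset("fig3")


def ensemble_config(preset, seed=TEST_SEED, n_spores=None, **overrides):
    return EnsembleConfig(
        gamma=GammaSpec(preset.gamma_shape, preset.gamma_scale),
        params=overrides.pop("params", preset.params),
        protocol=overrides.pop("protocol", preset.protocol),
        n_spores=n_spores or preset.n_spores,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def fig1_result(fig1):
    """Full 500-spore wild-type memory ensemble; shared across tests."""
    return run_ensemble(ensemble_config(fig1))


@pytest.fixture(scope="session")
def fig2c_result(fig2c):
    return run_ensemble(ensemble_config(fig2c), fit_draws=False)


@pytest.fixture(scope="session")
def fig2d_result(fig2d):
    return run_ensemble(ensemble_config(fig2d), fit_draws=False)


@pytest.fixture(scope="session")
def fig3_scan(fig3):
    """Deterministic GR copy-number scan 600..1800 step 50 with trajectories."""
    return gr_copy_scan(FIG3_SCAN_VALUES, fig3.params, fig3.protocol)
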