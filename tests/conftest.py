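"""Shared fixtures: tuned cell shapes and the desk-scale division ensembles.

The division ensembles are expensive (hundreds of full rounding-division-
fate replicates), so they are computed once per session and shared between
the tests that read different aspects of them.
"""

import numpy as np
import pytest

from shapemem.experiments import (
    EnsembleConfig,
    build_fixtures,
    run_division_ensemble,
    sweep_delta_dynamics,
)
from shapemem.synthetic_shapes import PAPER_ALONG_TARGETS

#: desk-scale study conditions (published scale is 144 replicates/shape)
DESK_REPLICATES = 48
BASE_SEED = 0
ASYMMETRIC = (0.052, 0.063, 0.092)


@pytest.fixture(scope="session")
def six_fixtures():
    """The six in-silico shapes, tuned to the published A_long values."""
    return build_fixtures(PAPER_ALONG_TARGETS)


@pytest.fixture(scope="session")
def asymmetric_fixtures(six_fixtures):
    return {k: six_fixtures[k] for k in ASYMMETRIC}


@pytest.fixture(scope="session")
def baseline_config():
    return EnsembleConfig(replicates=DESK_REPLICATES, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def baseline_ensemble(six_fixtures, baseline_config):
    """Baseline six-shape division ensemble (bias vs A_long)."""
    return run_division_ensemble(baseline_config, six_fixtures)


@pytest.fixture(scope="session")
def perturbation_table(asymmetric_fixtures, baseline_config):
    """The four Delta-dynamics perturbations on the asymmetric shapes."""
    return sweep_delta_dynamics(baseline_config, asymmetric_fixtures)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
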