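import warnings

import numpy as np
import pytest

import classim as ci

# observer calibration emits a warning when an architecture's noiseless
# ceiling caps the d'-target; that behaviour has its own test
warnings.filterwarnings("ignore", message=".*capping the calibration target.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def _calibrated(variant, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if variant == "max":
            base = ci.ObserverConfig(variant="max")
        else:
            base = ci.ObserverConfig.for_variant(variant)
        return ci.calibrated(base, rng=np.random.default_rng(seed))


@pytest.fixture(scope="session")
def template_config():
    """Variant #1 (linear template) at threshold-level intrinsic noise."""
    return _calibrated(1, 101)


@pytest.fixture(scope="session")
def energy_config():
    """Variant #2 (energy model) at threshold-level intrinsic noise."""
    return _calibrated(2, 102)


@pytest.fixture(scope="session")
def hybrid_config():
    """Variant #4 (two-branch, gain-controlled nonlinear branch)."""
    return _calibrated(4, 104)


@pytest.fixture(scope="session")
def max_config():
    """MAX-rule observer with its contrast-dependent read-out window."""
    return _calibrated("max", 105)
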