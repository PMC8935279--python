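import numpy as np
import pytest

from plantclock import (
    CouplingConfig,
    LightProtocol,
    TemplateGeometry,
    build_template,
    run_protocol,
)
from plantclock.fitting import FitSpec, observables
from plantclock.parameters import DEFAULT_PARAMS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220321)


@pytest.fixture(scope="session")
def default_observables():
    """Single-cell scoring observables of the packaged defaults.

    Full reference protocol: 60 d 12:12 LD -> 60 d LL -> 60 d DD, discarding
    the first 55 d of each condition.  Shared across tests (a few seconds).
    """
    return observables(DEFAULT_PARAMS, FitSpec())


@pytest.fixture(scope="session")
def small_geometry():
    """A reduced seedling (234 cells) with the same four-region anatomy."""
    return TemplateGeometry(
        cotyledon_w=6, cotyledon_h=8, hypocotyl_w=3, hypocotyl_h=10,
        root_h=30, root_tip_h=6,
    )


@pytest.fixture(scope="session")
def small_template(small_geometry):
    return build_template(small_geometry)


@pytest.fixture(scope="session")
def release_protocol():
    """The reference spatial protocol: 4 d 12:12 LD then 6 d LL."""
    return LightProtocol(
        "LD_ideal", entrain_days=4, release_kind="LL", release_days=6
    )


@pytest.fixture(scope="session")
def reference_spatial_run(release_protocol):
    """Full-template LL release run at the reference coupling (J_local = 2)."""
    return run_protocol(
        build_template(), CouplingConfig(J_local=2.0), release_protocol,
        seed=3, record=("cP97m",),
    )
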