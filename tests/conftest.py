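import numpy as np
import pytest

from stcar.lattice import make_grid_lattice, temporal_path_lattice
from stcar.models import ModelSpec, PriorSpec
from stcar.panel import SpaceTimePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid22():
    return make_grid_lattice(2, 2)


@pytest.fixture
def path3():
    return temporal_path_lattice(3)


@pytest.fixture
def tiny_panel(rng):
    """2 areas x 3 years, one covariate, for plumbing tests."""
    D, T = 2, 3
    return SpaceTimePanel(
        n_areas=D,
        n_times=T,
        response=rng.normal(size=D * T),
        covariates={"temperature": 20.0 + rng.uniform(size=D * T)},
        area_labels=("a", "b"),
        time_labels=("2004", "2005", "2006"),
    )


@pytest.fixture
def default_prior():
    return PriorSpec()


@pytest.fixture
def anova_spec():
    return ModelSpec(family="st_anova", covariates=("temperature",))
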