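"""Shared fixtures: the validation demography at simulation scale and the
corresponding model objects in mutation units."""

import numpy as np
import pytest

from ilshmm.demography import DemographyParams, coalescent_units, rescale
from ilshmm.discretization import default_cutpoints
from ilshmm.emissions import HmmModel
from ilshmm.simulate import DEFAULT_MU, default_simulation_params, simulate_alignment

MU = DEFAULT_MU


@pytest.fixture(scope="session")
def sim_params() -> DemographyParams:
    """Validation demography in natural units (haploid-convention sizes)."""
    return default_simulation_params()


@pytest.fixture(scope="session")
def model_params(sim_params) -> DemographyParams:
    """Same demography in mutation units."""
    return rescale(sim_params, 1.0 / MU)


@pytest.fixture(scope="session")
def grid33(model_params):
    return default_cutpoints(3, 3, coalescent_units(model_params).T2)


@pytest.fixture(scope="session")
def grid11(model_params):
    return default_cutpoints(1, 1, coalescent_units(model_params).T2)


@pytest.fixture(scope="session")
def model33(model_params, grid33) -> HmmModel:
    return HmmModel(model_params, grid33)


@pytest.fixture(scope="session")
def model11(model_params, grid11) -> HmmModel:
    return HmmModel(model_params, grid11)


@pytest.fixture(scope="session")
def sim100kb(sim_params):
    """One 100-kb simulated alignment with truth tracks."""
    return simulate_alignment(sim_params, 100_000, mu=MU, seed=42)


@pytest.fixture(scope="session")
def decoded100kb(model33, sim100kb):
    return model33.posterior(sim100kb.codes())
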