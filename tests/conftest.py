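import warnings

import numpy as np
import pytest

from scatterbayes.wave_forward import (
    DomainSpec,
    MediumFields,
    Mesh,
    ObservationGrid,
    ResolutionWarning,
    SourceSpec,
)


@pytest.fixture(autouse=True)
def _quiet_resolution_warnings():
    """Coarse fixture meshes legitimately trip the resolution warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ResolutionWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tissue_domain():
    return DomainSpec((-5.0, 5.0), (-5.0, 0.0))


@pytest.fixture
def tissue_mesh(tissue_domain):
    return Mesh.structured(tissue_domain, 0.25)


@pytest.fixture
def tissue_medium(tissue_mesh):
    return MediumFields.homogeneous(tissue_mesh, 1.0, 1.69)


@pytest.fixture
def tissue_source():
    return SourceSpec(amplitude=1.0, peak_frequency=0.5, kappa=2.0, centers=[(0.0, 0.0)])


@pytest.fixture
def surface_observation():
    recs = np.column_stack([np.linspace(-3.0, 3.0, 7), np.zeros(7)])
    return ObservationGrid(recs, np.arange(1.0, 6.0 + 1e-9, 0.05))
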