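import numpy as np
import pytest

import golgisim.morphology as morph
from golgisim import solver


@pytest.fixture(scope="session")
def compact_morphology():
    m = morph.make_surrogate(morph.SurrogateParams.compact(), seed=1)
    morph.discretize(m, 40.0)
    return m


@pytest.fixture(scope="session")
def cell(compact_morphology):
    """Full Golgi cell model on the compact surrogate morphology."""
    return solver.build_cell(compact_morphology)


@pytest.fixture(scope="session")
def passive_cell(compact_morphology):
    """Same geometry with all active channels stripped."""
    return solver.build_cell(compact_morphology).copy_with(placements=[])


@pytest.fixture(scope="session")
def soma_sphere():
    """Isopotential single-compartment passive model (area from the soma)."""
    m = morph.make_surrogate(morph.SurrogateParams.compact(), seed=1)
    soma = morph.Section("soma", list(m.soma.points))
    iso = morph.Morphology([soma])
    morph.discretize(iso, 40.0)
    cellm = solver.build_cell(iso).copy_with(placements=[])
    cellm.passive["el"] = {"*": -70.0}
    return cellm
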