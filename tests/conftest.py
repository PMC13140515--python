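import numpy as np
import pytest

from sprcorona import InstrumentModel, kretschmann_stack
from sprcorona.optics import OpticalLayer, OpticalStack


@pytest.fixture(scope="session")
def gold_stack():
    """Bare gold sensor in water: prism 1.515 | Au 50 nm | water 1.333."""
    return kretschmann_stack()


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def coarse_instrument():
    """0.05 deg grid: same window, 4x fewer points, for speed-bound tests."""
    return InstrumentModel(angle_step=0.05)


def random_stack(rng, n_layers=None):
    """Random passive multilayer for oracle-equivalence checks."""
    n_layers = n_layers if n_layers is not None else rng.integers(1, 6)
    layers = [OpticalLayer("prism", None, {0.0: complex(rng.uniform(1.4, 1.8))})]
    for i in range(n_layers):
        n = rng.uniform(1.0, 4.0) + 1j * rng.uniform(0.0, 4.0)
        layers.append(OpticalLayer(f"l{i}", rng.uniform(1.0, 200.0), {0.0: n}))
    layers.append(OpticalLayer("ambient", None, {0.0: complex(rng.uniform(1.0, 1.5))}))
    # key the dispersion maps by the evaluation wavelength
    wl = rng.uniform(500.0, 900.0)
    layers = [
        OpticalLayer(l.name, l.thickness, {wl: l.refractive_index[0.0]})
        for l in layers
    ]
    return OpticalStack(layers), wl
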