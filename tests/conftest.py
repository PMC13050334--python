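import numpy as np
import pytest

from ect1d.complex_model import SampledCurve, reparam_constant_velocity
from ect1d.ect_core import uniform_directions
from ect1d.synth_shapes import make_circle, random_fourier_spec, make_fourier_curve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dirs8():
    return uniform_directions(8)


@pytest.fixture
def dirs64():
    return uniform_directions(64)


@pytest.fixture
def unit_circle():
    return make_circle(1.0, 2000)


@pytest.fixture
def fourier_curve():
    """A fixed smooth closed curve used across modules."""
    return make_fourier_curve(random_fourier_spec(seed=7, n_samples=800))


def random_open_curve(seed: int, n: int = 400) -> SampledCurve:
    """Smooth open planar curve from a few random Fourier modes."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    x = t.copy()
    y = np.zeros_like(t)
    for k in range(1, 4):
        x = x + rng.normal(0, 0.1) / k**2 * np.sin(np.pi * k * t)
        y = y + rng.normal(0, 0.3) / k**2 * np.sin(np.pi * k * t + rng.uniform(0, np.pi))
    return SampledCurve(t, np.column_stack([x, y]))


def constant_velocity_fourier(seed: int, n: int = 600):
    """Closed Fourier curve resampled to constant speed."""
    X = make_fourier_curve(random_fourier_spec(seed=seed, n_samples=n))
    curve = reparam_constant_velocity(X.curves["e0"], n)
    from ect1d.complex_model import single_curve_complex

    return single_curve_complex(curve, closed=True)
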