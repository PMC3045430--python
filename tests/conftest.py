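import numpy as np
import pytest

from mrnaturnover.kinetics_core import DEFAULT_GRID, GeneKinetics, TimeGrid


@pytest.fixture
def grid() -> TimeGrid:
    return DEFAULT_GRID


@pytest.fixture
def steady_gene(grid) -> GeneKinetics:
    """A gene at global steady state: TR = 1, RA = 10, kd0 = 0.1."""
    n = len(grid)
    return GeneKinetics("steady", grid, np.ones(n), np.full(n, 10.0))


def rk4_forward(ra1, tr1, tr2, kd, dt, n_steps=20000):
    """Independent fixed-step RK4 integration of dRA/dt = TR(t) - kd*RA.

    TR varies linearly from tr1 to tr2 over [0, dt].  Vectorized over
    equally shaped array arguments.
    """
    ra1, tr1, tr2, kd, dt = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (ra1, tr1, tr2, kd, dt))
    )
    h = dt / n_steps
    y = ra1.copy()
    slope = (tr2 - tr1) / dt

    def f(t, y):
        return tr1 + slope * t - kd * y

    t = np.zeros_like(y)
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + h
    return y
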