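import numpy as np
import pytest

from lprosy.spin import build_spin_system


@pytest.fixture
def solomon_pair():
    """Two equal pools coupled only by cross-relaxation (rho=1, sigma=0.3)."""
    return build_spin_system(
        {
            "pools": {
                "A": {"kind": "labile", "m_eq": 1.0, "r1": 1.0},
                "B": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.0},
            },
            "sigma": {"A-B": 0.3},
        }
    )


@pytest.fixture
def sugar_system():
    """OH/water/CH system at a fixed mid-range exchange rate."""
    return build_spin_system(
        {
            "pools": {
                "OH": {"kind": "labile", "m_eq": 1.0, "r1": 1.0, "r2": 20.0,
                       "offset": 1500.0},
                "W": {"kind": "water", "m_eq": 1000.0, "r1": 0.3, "r2": 1.0},
                "CH": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.2, "r2": 8.0},
            },
            "exchange": {"OH-W": 200.0},
            "sigma": {"OH-CH": -0.05},
            "j": {"OH-CH": 5.0},
        }
    )


@pytest.fixture
def gentle_system():
    """Slow-rate three-pool system for brute-force integrator comparisons."""
    return build_spin_system(
        {
            "pools": {
                "OH": {"kind": "labile", "m_eq": 1.0, "r1": 0.8},
                "W": {"kind": "water", "m_eq": 50.0, "r1": 0.3},
                "CH": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.1},
            },
            "exchange": {"OH-W": 2.0},
            "sigma": {"OH-CH": -0.2},
        }
    )


@pytest.fixture
def no_exchange_jpair():
    """Labile/nonlabile J-coupled pair, no water pool, weak relaxation."""
    return build_spin_system(
        {
            "pools": {
                "OH": {"kind": "labile", "m_eq": 1.0, "r1": 0.1, "r2": 0.1},
                "CH": {"kind": "nonlabile", "m_eq": 1.0, "r1": 0.1, "r2": 0.1},
            },
            "j": {"OH-CH": 5.0},
        }
    )


def brute_force_propagate(A, b, m0, t, dt=1e-5):
    """Fixed-step RK4 integration of dM/dt = A M + b (independent oracle)."""
    m = np.asarray(m0, dtype=float).copy()
    steps = int(round(t / dt))

    def f(x):
        return A @ x + b

    for _ in range(steps):
        k1 = f(m)
        k2 = f(m + 0.5 * dt * k1)
        k3 = f(m + 0.5 * dt * k2)
        k4 = f(m + dt * k3)
        m = m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return m
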