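"""Shared fixtures and the independent brute-force Bloch integrator oracle."""

from __future__ import annotations

import numpy as np
import pytest

from micest.core import PoolParameters, SaturationPulse, ScannerContext


@pytest.fixture(scope="session")
def ctx() -> ScannerContext:
    return ScannerContext()  # 9.4 T


@pytest.fixture(scope="session")
def water() -> PoolParameters:
    return PoolParameters("water", t1=1.8, t2=0.040)


@pytest.fixture(scope="session")
def hydroxyl() -> PoolParameters:
    # myoinositol-like -OH pool: +0.6 ppm, k = 600 1/s
    return PoolParameters("hydroxyl", t1=1.0, t2=0.010, shift=0.6,
                          fraction=0.0037324, k_exchange=600.0)


@pytest.fixture(scope="session")
def mt_pool() -> PoolParameters:
    return PoolParameters("macromolecular", t1=1.0, t2=0.0005, shift=-2.4,
                          fraction=0.001, k_exchange=40.0)


@pytest.fixture(scope="session")
def cest_pulse() -> SaturationPulse:
    return SaturationPulse(b1=0.9, duration=1.6)


@pytest.fixture(scope="session")
def wassr_pulse() -> SaturationPulse:
    return SaturationPulse(b1=0.1, duration=0.5)


def rk4_zvalue(
    pools,
    pulse: SaturationPulse,
    offset_ppm: float,
    context: ScannerContext,
    dt: float = 1e-5,
) -> float:
    """Fixed-step RK4 integration of the Bloch-McConnell ODE from equilibrium.

    Deliberately naive (no matrix exponential, no linear solve): serves as
    the independent oracle for the production engine.
    """
    n = len(pools)
    w1 = 2.0 * np.pi * context.gamma_bar * pulse.b1

    def deriv(m: np.ndarray) -> np.ndarray:
        out = np.zeros_like(m)
        for i, p in enumerate(pools):
            r1, r2 = 1.0 / p.t1, 1.0 / p.t2
            dw = 2.0 * np.pi * context.hz_per_ppm * (p.shift - offset_ppm)
            mx, my, mz = m[3 * i], m[3 * i + 1], m[3 * i + 2]
            out[3 * i] += -r2 * mx + dw * my
            out[3 * i + 1] += -dw * mx - r2 * my + w1 * mz
            out[3 * i + 2] += -w1 * my - r1 * (mz - p.fraction)
        for j, p in enumerate(pools[1:], start=1):
            if p.k_exchange == 0:
                continue
            k, kw = p.k_exchange, p.fraction * p.k_exchange
            for c in range(3):
                out[c] += k * m[3 * j + c] - kw * m[c]
                out[3 * j + c] += kw * m[c] - k * m[3 * j + c]
        return out

    m = np.zeros(3 * n)
    for i, p in enumerate(pools):
        m[3 * i + 2] = p.fraction
    steps = int(round(pulse.duration / dt))
    for _ in range(steps):
        k1 = deriv(m)
        k2 = deriv(m + 0.5 * dt * k1)
        k3 = deriv(m + 0.5 * dt * k2)
        k4 = deriv(m + dt * k3)
        m = m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(m[2])
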