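"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from qnq import ModelParams, NoiseModel, Scenario
from qnq.synthetic import generate_plate_dataset


def rk4_integrate(rhs, y0, t_end, dt, breakpoints=()):
    """Fixed-step classical RK4 oracle, independent of the production solver.

    ``breakpoints`` (times commensurate with ``dt``) split the integration
    so a discontinuous right-hand side is never straddled by a step.
    """
    y = np.asarray(y0, dtype=float).copy()
    edges = [0.0, *sorted(b for b in breakpoints if 0.0 < b < t_end), t_end]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        n = int(round((t1 - t0) / dt))
        assert abs(n * dt - (t1 - t0)) < 1e-9, "breakpoints must align with dt"
        t = t0
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
    return y


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def small_plate():
    """A small generated dataset: 3 culture types, 1 environment, 2 weeks."""
    scenarios = [
        Scenario(composition=c, environment="simple", starvation_weeks=2,
                 n_replicates=3)
        for c in ("Q", "NQ", "mixed")
    ]
    noise = NoiseModel(seed=42)
    return generate_plate_dataset(ModelParams(), scenarios, noise)


@pytest.fixture(scope="session")
def full_plate():
    """The full default plate layout (long + short protocols), default noise."""
    return generate_plate_dataset(ModelParams(), noise=NoiseModel(seed=7))
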