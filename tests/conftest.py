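"""Shared fixtures and the independent least-squares oracle.

The oracle fits a line by iteratively refined grid search over
(slope, intercept), minimizing the sum of squared residuals directly; it
shares no code path with the scipy-based fits it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from quenchbind import simulate as sim


def grid_search_line(x, y, rounds: int = 12, grid: int = 41):
    """Brute-force least-squares line fit by shrinking grid search."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    # start from a generous box around a crude moment estimate
    sx = x.std() or 1.0
    slope0 = ((x - x.mean()) * (y - y.mean())).sum() / (((x - x.mean()) ** 2).sum() or 1.0)
    icept0 = y.mean() - slope0 * x.mean()
    s_half = max(abs(slope0), 1.0)
    i_half = max(abs(icept0), 1.0)
    best = (slope0, icept0)
    for _ in range(rounds):
        slopes = np.linspace(best[0] - s_half, best[0] + s_half, grid)
        icepts = np.linspace(best[1] - i_half, best[1] + i_half, grid)
        sse = ((y[None, None, :] - slopes[:, None, None] * x[None, None, :]
                - icepts[None, :, None]) ** 2).sum(axis=2)
        i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
        best = (float(slopes[i]), float(icepts[j]))
        s_half /= grid / 4
        i_half /= grid / 4
    return best


@pytest.fixture
def static_series():
    """Noise-free paper-like static titration: Kb = 2.07e4 M^-1, n = 1."""
    series, _ = sim.generate_titration(sim.GroundTruth(kb=2.07e4, n=1.0))
    return series


@pytest.fixture
def dynamic_series():
    """Noise-free dynamic titration: Ksv = 2.0e4 M^-1 at 298 K."""
    series, _ = sim.generate_titration(
        sim.GroundTruth(mechanism="dynamic", ksv=2.0e4)
    )
    return series
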