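"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from mifkit import synthetic


def grid_rate_oracle(series, r_min=0.01, r_max=300.0, step=0.01):
    """Exhaustive grid search over decay rates, amplitude profiled out.

    For each candidate R the optimal amplitude is A*(R) = (h.e)/(e.e)
    with e = exp(-R t); the SSE then is h.h - A*^2 (e.e).  Independent of
    the package's optimizer: pure enumeration.
    """
    grid = np.arange(r_min, r_max + step / 2, step)
    t_s = series.delays_ms / 1000.0
    h = series.heights
    e = np.exp(-np.outer(grid, t_s))          # (n_grid, n_points)
    ee = np.einsum("ij,ij->i", e, e)
    he = e @ h
    sse = h @ h - he ** 2 / ee
    return float(grid[np.argmin(sse)])


def normal_equation_ols(x, y):
    """Closed-form simple OLS via the normal equations (test oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_force_csp_threshold(deltas, trim_fraction=0.10, k_sigma=1.5,
                              sigma_mode="full"):
    """Hand-coded trimmed-mean threshold: explicit sort/drop loops."""
    vals = sorted(float(d) for d in deltas)
    n = len(vals)
    k = int(np.floor(n * trim_fraction))
    trimmed = vals[k:n - k] if k else vals
    mean = sum(trimmed) / len(trimmed)
    pool = vals if sigma_mode == "full" else trimmed
    pm = sum(pool) / len(pool)
    sigma = (sum((v - pm) ** 2 for v in pool) / (len(pool) - 1)) ** 0.5
    return mean, sigma, mean + k_sigma * sigma


@pytest.fixture
def default_truth():
    return synthetic.GroundTruth.default(n_residues=100, seed=0)


@pytest.fixture
def small_truth():
    return synthetic.GroundTruth.default(n_residues=20, seed=1,
                                         n_hotspots=3, n_broadened=2)
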