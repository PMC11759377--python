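"""Shared fixtures and the independent OLS oracle used across the suite."""

import numpy as np
import pytest

import healthscaling as hs


def ols_normal_equations(x, y):
    """Brute-force simple-regression solve from raw sums.

    Independent of scipy/statsmodels: slope and intercept straight from the
    normal equations, so library-backed fits can be checked against it.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def ols_slope_ci(x, y, level=0.95):
    """Two-sided OLS slope confidence interval from first principles."""
    from scipy.stats import t

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    slope, intercept = ols_normal_equations(x, y)
    resid = y - (intercept + slope * x)
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = (s2 / sxx) ** 0.5
    half = t.ppf(0.5 + level / 2, n - 2) * se
    return slope - half, slope + half


@pytest.fixture(scope="session")
def default_config():
    return hs.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_panel(default_config):
    return hs.generate_panel(default_config)


@pytest.fixture(scope="session")
def noiseless_panel():
    cfg = hs.SyntheticConfig(
        noise_sd=0.0, true_b_beds=1.2, true_b_doctors=0.9, seed=3
    )
    return hs.generate_panel(cfg)
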