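import math

import numpy as np
import pytest

from fitcloud.allocator import AllocatorConfig
from fitcloud.workload import PatternSpec, generate_series
from fitcloud import simulator


def brute_poisson_table(lam: float, k_max: int):
    """Independent Poisson oracle: term-by-term log-space summation.

    Returns (pmf, cdf) arrays for k = 0..k_max, computed without scipy's
    distribution machinery.
    """
    pmf = np.empty(k_max + 1)
    for k in range(k_max + 1):
        if lam == 0:
            pmf[k] = 1.0 if k == 0 else 0.0
        else:
            pmf[k] = math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
    return pmf, np.cumsum(pmf)


@pytest.fixture(scope="session")
def default_config() -> AllocatorConfig:
    """The simulation-study configuration: C=100, thresholds 0.2, w=5,
    1..150 units, step bound I equal to the unit cap."""
    return AllocatorConfig()


@pytest.fixture(scope="session")
def pattern_summaries(default_config):
    """Simulate all four default noise-free patterns once per session."""
    out = {}
    for kind in ("linear", "logarithmic", "repetitive", "combined"):
        series = generate_series(PatternSpec(kind))
        out[kind] = simulator.summarize(simulator.run(series, default_config))
    return out
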