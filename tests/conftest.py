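"""Shared fixtures: model parameter sets and cached evolution replicates.

The birth-death evolution replicates are expensive, so they are computed
once per session and shared between the module tests and the acceptance
suite.  All seeds are fixed; every fixture is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from twopac.core import TwoPhaseParams
from twopac.evolution import EvoConfig, run_bd_evolution

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> TwoPhaseParams:
    """Reference two-phase parameter set used across the suite."""
    return TwoPhaseParams(a=0.004, t0=10.0, k=0.3)


@pytest.fixture(scope="session")
def standard_gap_runs():
    """Ten replicates of the standard evolution condition (founders 2/2)."""
    return [
        run_bd_evolution(EvoConfig(seed=s, t_max=400.0)) for s in range(10)
    ]


@pytest.fixture(scope="session")
def opposed_gap_runs():
    """Replicates started from opposed trait orderings.

    Side "below": founders with senescence onset well before the end of
    fertility (x_d < x_b).  Side "above": founders with the opposite
    ordering (x_d > x_b).  Five seeds each, long horizon (convergence from
    above is slow: the onset-age cloud is dragged upward by selection
    against its sub-fertile tail, so the run must be generous).
    """
    below = [
        run_bd_evolution(EvoConfig(seed=20 + s, x_b0=2.5, x_d0=1.0, t_max=800.0))
        for s in range(5)
    ]
    above = [
        run_bd_evolution(EvoConfig(seed=30 + s, x_b0=1.5, x_d0=2.5, t_max=800.0))
        for s in range(5)
    ]
    return {"below": below, "above": above}


#: Fertility-intensity sweep levels with carrying capacities chosen so the
#: founder-trait equilibrium population is near 500 in every arm.
SWEEP_LEVELS = ((1.0, 1000.0), (1.5, 750.0), (2.0, 667.0), (4.0, 571.0), (8.0, 533.0))


@pytest.fixture(scope="session")
def ib_sweep_runs():
    """Ten replicates per fertility-intensity level, common founders."""
    out = {}
    for i_b, cap in SWEEP_LEVELS:
        out[i_b] = [
            run_bd_evolution(
                EvoConfig(seed=40 + s, i_b=i_b, K=cap, t_max=250.0)
            )
            for s in range(10)
        ]
    return out


@pytest.fixture(scope="session")
def exploration_runs():
    """Paired runs: fast-turnover vs slow-turnover life histories.

    High fertility intensity with a short fertile period against low
    intensity with a long one, equal mutation parameters, ten seed pairs.
    """
    hi = [
        run_bd_evolution(
            EvoConfig(seed=60 + s, i_b=4.0, K=667.0, x_b0=1.0, x_d0=1.0, t_max=150.0)
        )
        for s in range(10)
    ]
    lo = [
        run_bd_evolution(
            EvoConfig(seed=60 + s, i_b=1.0, K=667.0, x_b0=4.0, x_d0=4.0, t_max=150.0)
        )
        for s in range(10)
    ]
    return {"hi": hi, "lo": lo}


def ks_distance(samples: np.ndarray, cdf) -> float:
    """Exact one-sample Kolmogorov-Smirnov statistic."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    F = cdf(x)
    upper = np.max(np.arange(1, n + 1) / n - F)
    lower = np.max(F - np.arange(0, n) / n)
    return float(max(upper, lower))
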