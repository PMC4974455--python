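"""Shared fixtures: the seeded 1-D benchmark and its reconstruction scans.

Heavy objects are session-scoped so the overfitting/fidelity/robustness
properties can share one set of reconstructions.
"""

from __future__ import annotations

import numpy as np
import pytest

from rnoise.clean import CleanConfig, clean_threshold_scan
from rnoise.ist import IstConfig, ist_reconstruct
from rnoise.synth import SimulationParams, simulate_benchmark
from rnoise.transforms import hyper_magnitude, zero_fill_transform
from rnoise.variational import DEFAULT_LAMBDAS, VariationalConfig, lambda_scan

#: One fixed seed for every benchmark-derived test in the suite.
BENCH_SEED = 11


@pytest.fixture(scope="session")
def bench():
    """Default nine-signal noisy benchmark with its 80/20 split."""
    return simulate_benchmark(SimulationParams(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def noiseless_bench():
    """Noiseless, non-decaying, on-grid variant: the parameter-recovery oracle."""
    df = 10_000.0 / 1024
    freqs = tuple(round(f / df) * df for f in np.linspace(-4000, 4000, 9))
    params = SimulationParams(
        seed=BENCH_SEED, noise_sigma=0.0, decay_rate_hz=0.0, frequencies_hz=freqs
    )
    return params, simulate_benchmark(params)


@pytest.fixture(scope="session")
def l1_scan(bench):
    return lambda_scan(
        bench.split,
        bench.noise_ref,
        bench.reference,
        DEFAULT_LAMBDAS,
        VariationalConfig(regularizer="l1"),
    )


@pytest.fixture(scope="session")
def maxent_scan(bench):
    from rnoise.benchmark import suggest_maxent_scale

    cfg = VariationalConfig(
        regularizer="maxent", maxent_scale=suggest_maxent_scale(bench.split.working)
    )
    return lambda_scan(bench.split, bench.noise_ref, bench.reference, DEFAULT_LAMBDAS, cfg)


@pytest.fixture(scope="session")
def ist_result(bench):
    return ist_reconstruct(bench.split, bench.noise_ref, IstConfig(), reference=bench.reference)


@pytest.fixture(scope="session")
def clean_scan(bench):
    dirty = zero_fill_transform(bench.split.working)
    top = 1.05 * float(np.max(np.abs(dirty.data)))
    floor = float(np.mean(hyper_magnitude(bench.noise_ref.values)))
    thresholds = tuple(np.geomspace(top, floor / 10.0, 30).tolist())
    cfg = CleanConfig(gain=0.1, threshold_scan=thresholds)
    return clean_threshold_scan(bench.split, bench.noise_ref, cfg, reference=bench.reference)
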