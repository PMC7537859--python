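import numpy as np
import pytest

import periodscope as ps


@pytest.fixture(scope="session")
def planted_150kb():
    """Small planted genome (period 10.5) plus its truth sidecar."""
    genome, truth = ps.planted_genome(
        150_000, period=10.5, motif="AA", density=3.0, jitter=1.0, gc=0.5, seed=7
    )
    return genome, truth


@pytest.fixture(scope="session")
def planted_fit(planted_150kb):
    """Pooled histogram, smoothed series, autocorrelation and free fit."""
    genome, _ = planted_150kb
    h = ps.pooled_histogram(genome)
    series = ps.smooth(h)
    ac = ps.autocorrelate(series)
    fit = ps.fit_damped_sine(ac)
    return h, series, ac, fit


@pytest.fixture(scope="session")
def random_60kb():
    return ps.GenomeRecord(
        id="null", sequence=ps.random_genome(60_000, gc=0.5, seed=13)
    )
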