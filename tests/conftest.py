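import numpy as np
import pytest

from cgmard import (
    GlucoseTrace,
    PairedDataset,
    ProtocolConfig,
    ReferenceDistribution,
    generate_cohort,
    generate_range_dependent_cohort,
)


@pytest.fixture(scope="session")
def protocol_cohort():
    """Default 12-subject, 7-day truth BG cohort (fixed seed)."""
    return generate_cohort(ProtocolConfig(), seed=1)


@pytest.fixture(scope="session")
def range_cohort():
    """Paired cohort with range-dependent CGM error (fixed seed)."""
    return generate_range_dependent_cohort(n=3000, seed=7)


@pytest.fixture(scope="session")
def dense_paired_12pct():
    """Dense paired dataset with ~12% MARD: log-normal references,
    15% relative Gaussian sensor error (half-normal mean 11.97%)."""
    rng = np.random.default_rng(3)
    n = 4000
    pref = ReferenceDistribution()
    ref = pref.rvs(n, rng=rng)
    cgm = np.maximum(ref * (1 + 0.15 * rng.normal(size=n)), 1.0)
    return PairedDataset(times=np.arange(n, dtype=float), cgm_values=cgm, ref_values=ref)


@pytest.fixture()
def simple_paired():
    return PairedDataset(
        times=[0.0, 5.0, 10.0],
        cgm_values=[110.0, 95.0, 100.0],
        ref_values=[100.0, 100.0, 100.0],
    )


@pytest.fixture()
def flat_trace():
    return GlucoseTrace(values=np.full(50, 150.0), sampling_interval=5.0)
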