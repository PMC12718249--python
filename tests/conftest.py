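import numpy as np
import pytest

import dyadsync
from dyadsync import rsa as rsalib


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-dyad cohort at default settings, shared across tests."""
    return dyadsync.generate_cohort(dyadsync.SimulationConfig(n_dyads=6, seed=42))


@pytest.fixture(scope="session")
def cohort_epochs(small_cohort):
    """RSA epoch means + baseline references for the shared cohort."""
    out = {}
    for d in small_cohort.dyads:
        m = rsalib.ibi_to_rsa_epochs(d.mother_ibi, rsalib.ADULT_BAND)
        c = rsalib.ibi_to_rsa_epochs(d.child_ibi, rsalib.CHILD_BAND)
        out[d.dyad_id] = dict(mother_epochs=m.epoch_means, child_epochs=c.epoch_means,
                              mother_baseline=m.baseline_reference,
                              child_baseline=c.baseline_reference)
    return out


def constant_ibi_series(ibi_ms=800.0, duration_s=300.0, **kw):
    beats = np.arange(0.0, duration_s, ibi_ms / 1000.0)
    return rsalib.IbiSeries(beat_times=beats, **kw)
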