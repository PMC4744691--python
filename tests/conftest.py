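import numpy as np
import pytest

from cavitrace import AEHit, AESeries, PsiSeries, load_reference_panel


@pytest.fixture(scope="session")
def panel():
    """The packaged 18-entry species panel."""
    return load_reference_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(times_min, amps=None, t_end_min=None):
    """Build an AESeries from hit times in minutes."""
    times_min = np.sort(np.asarray(times_min, dtype=float))
    if amps is None:
        amps = np.full(len(times_min), 60.0)
    hits = [
        AEHit(time_s=float(t * 60.0), amplitude_db=float(a))
        for t, a in zip(times_min, amps)
    ]
    t_end_s = None if t_end_min is None else t_end_min * 60.0
    return AESeries(hits=hits, t_end_s=t_end_s)


def make_psi(readings_min):
    """Build a PsiSeries from (time_min, psi) pairs."""
    return PsiSeries(readings=[(t * 60.0, p) for t, p in readings_min])
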