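import numpy as np
import pytest
from hypothesis import settings

from chaoscalc.synthetic import HookeanMembraneModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from chaoscalc.tension import PressureTrace, TensionEstimate


@pytest.fixture
def noiseless_reference():
    return HookeanMembraneModel(noise_amp=0.0)


@pytest.fixture
def noiseless_peptide():
    return HookeanMembraneModel(dA_p=0.5, softening=0.9, noise_amp=0.0)


@pytest.fixture
def noisy_reference():
    return HookeanMembraneModel(noise_amp=50.0)


@pytest.fixture
def noisy_peptide():
    return HookeanMembraneModel(dA_p=0.5, softening=0.9, noise_amp=50.0)


def make_trace(pxx, pyy, pzz, lz=10.0, area=46.0, dt=10.0, **kw):
    pxx = np.atleast_1d(np.asarray(pxx, dtype=float))
    n = pxx.size
    return PressureTrace(
        time=dt * np.arange(n),
        pxx=pxx,
        pyy=np.broadcast_to(np.asarray(pyy, dtype=float), (n,)),
        pzz=np.broadcast_to(np.asarray(pzz, dtype=float), (n,)),
        lz=lz,
        area=area,
        **kw,
    )


def exact_estimate(sigma, area, sem=0.0):
    return TensionEstimate(
        sigma=sigma, sem=sem, n_blocks=1, n_frames_used=1, t_discard=0.0, area=area
    )
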