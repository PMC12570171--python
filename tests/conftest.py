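import numpy as np
import pytest

from atrialep import mesh, synth


@pytest.fixture(scope="session")
def flat_mesh_fine():
    """40x40 mm flat sheet at 1 mm vertex spacing."""
    return mesh.flat_rectangle(40.0, 40.0, 1.0)


@pytest.fixture(scope="session")
def planar_wave(flat_mesh_fine):
    """Noise-free planar wavefront dataset at 0.5 m/s."""
    spec = synth.WavefrontSynthSpec(mesh=flat_mesh_fine,
                                    electrode_density_per_cm2=15.0,
                                    wave_kind="planar", speed_m_per_s=0.5,
                                    seed=3)
    return synth.gen_wavefront(spec)


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 30-s 12-lead ECG at 60 bpm."""
    spec = synth.EcgSynthSpec(duration_s=30.0, heart_rate_bpm=60.0,
                              noise_sd_mv=0.0, powerline_hz=None, seed=0)
    return synth.gen_ecg(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
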