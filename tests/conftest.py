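import numpy as np
import pytest

from valveforge import geometry as geo
from valveforge import synthesis as syn
from valveforge import waveform as wfm


@pytest.fixture(scope="session")
def default_params():
    return geo.RootGeometryParams()


@pytest.fixture(scope="session")
def default_profile(default_params):
    return geo.build_root_profile(default_params)


@pytest.fixture(scope="session")
def tube_params():
    """Degenerate equal-diameter geometry: a straight tube, inner radius
    10 mm, total length 50 mm."""
    return geo.RootGeometryParams(
        annulus_diameter=20.0, sinus_max_diameter=20.0,
        sinotubular_diameter=20.0, ascending_aorta_diameter=20.0,
        lvot_diameter=20.0, lvot_length=10.0, sinus_height=20.0,
        ascending_aorta_length=20.0)


@pytest.fixture(scope="session")
def tube_profile(tube_params):
    return geo.build_root_profile(tube_params)


@pytest.fixture(scope="session")
def default_waveform():
    return wfm.make_aortic_waveform()


def constant_waveform(q0: float, period: float = 1.0) -> wfm.FlowWaveform:
    times = np.arange(100) * (period / 100)
    return wfm.FlowWaveform(
        times=times, q=np.full(100, q0), period=period,
        q_fn=lambda t: np.full_like(np.asarray(t, dtype=np.float64), q0),
        peak_flow=q0)


@pytest.fixture(scope="session")
def tube_steady_field(tube_profile):
    """Steady Poiseuille flow at q = 10π mL/s in the straight tube:
    centerline velocity 2q/(πR²) = 20 cm/s."""
    w = constant_waveform(10.0 * np.pi)
    acq = syn.AcquisitionParams.default_4d(tube_profile, n=64, n_frames=2)
    return syn.sample_velocity_field(tube_profile, w, acq)


@pytest.fixture(scope="session")
def phantom_field(default_profile, default_waveform):
    """Noise-free pulsatile 4D dataset over the default phantom
    (desk-scale grid)."""
    acq = syn.AcquisitionParams.default_4d(default_profile, n=48,
                                           n_frames=16)
    return syn.sample_velocity_field(default_profile, default_waveform, acq)


@pytest.fixture(scope="session")
def vortex_zoom_field(default_profile, default_waveform):
    """Fine grid over one sinus, vortex only (no bulk flow)."""
    vx = syn.VortexParams()
    centers, tangents = syn.vortex_centers(default_profile, vx)
    c = centers[0]
    n, box = 64, 14.0
    vox = box / n
    acq = syn.AcquisitionParams(
        voxel_size=(vox,) * 3, field_of_view=(box,) * 3,
        matrix_size=(n,) * 3, n_frames=8,
        origin=tuple(c - box / 2 + vox / 2))
    f = syn.sample_velocity_field(default_profile, default_waveform, acq,
                                  vortex=vx, shape="none")
    return f, vx, centers, tangents
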