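import numpy as np
import pytest

import beamgait as bg

# speed-domain tracking noise at 5% of the swing peak: the foot swing
# advances one stride (5 cm) over a 7-frame swing, peak speed 2*5/7
SWING_PEAK = 2 * 5.0 / 7
NOISE_SD = 0.05 * SWING_PEAK / np.sqrt(2)


@pytest.fixture(scope="session")
def clean_gait():
    """Noiseless, jitter-free default gait (period 20, 10 cycles)."""
    spec = bg.GaitSpec()
    pose, truth = bg.simulate_gait(spec)
    return spec, pose, truth


@pytest.fixture(scope="session")
def clean_speed(clean_gait):
    _, pose, _ = clean_gait
    return bg.compute_speed(pose)


@pytest.fixture(scope="session")
def clean_swc(clean_gait, clean_speed):
    _, _, truth = clean_gait
    t0, tau0 = truth.boundaries[0]
    template = bg.select_template(clean_speed, t0, t0 + tau0)
    seg = bg.segment_cycles(clean_speed, template)
    return bg.compute_swc(clean_speed, seg), seg


@pytest.fixture(scope="session")
def stereo_45(clean_gait):
    _, pose, _ = clean_gait
    from beamgait.simulate import StereoRigSpec, project_stereo
    return project_stereo(pose, StereoRigSpec())


@pytest.fixture(scope="session")
def stereo_90(clean_gait):
    _, pose, _ = clean_gait
    from beamgait.simulate import StereoRigSpec, project_stereo
    return project_stereo(pose, StereoRigSpec(configuration="90"))
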