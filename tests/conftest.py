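import numpy as np
import pytest

from finbody.presets import preset
from finbody.simulate import generate_bout_table, render_epoch


@pytest.fixture(scope="session")
def noiseless_preset():
    """3 wpf preset with all measurement-independent noise removed."""
    p = preset("3wpf")
    p.attack_noise_sd = 0.0
    return p


@pytest.fixture(scope="session")
def rendered_fixture(noiseless_preset):
    """Small noiseless bout table rendered into a tracked epoch."""
    bouts = generate_bout_table(noiseless_preset, 12, seed=42)
    epoch = render_epoch(bouts, noiseless_preset, epoch_id="fix")
    return bouts, epoch


def make_epoch(time, x, z, posture, epoch_id="e"):
    from finbody.kinematics import TrackedEpoch

    return TrackedEpoch(epoch_id=epoch_id, time=np.asarray(time, float),
                        x=np.asarray(x, float), z=np.asarray(z, float),
                        posture=np.asarray(posture, float))
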