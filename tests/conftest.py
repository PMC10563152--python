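import numpy as np
import pytest

from apobd import SimConfig, simulate_video


def cell_union(cells, t, shape):
    """Union of all cell masks present in frame t."""
    out = np.zeros(shape, dtype=bool)
    for c in cells:
        if c.present(t):
            out |= np.asarray(c.masks[t], dtype=bool)
    return out


@pytest.fixture(scope="session")
def event_sim():
    """A 128x128 killing-event video: onset at frame 3, 8 frames."""
    cfg = SimConfig(
        image_size=(128, 128),
        n_effectors=1,
        n_targets=2,
        apobd_area_px=(30.0, 150.0),
        apobd_count_at_burst=(4, 6),
        onset_frame=3,
        n_frames=8,
        contact_frames=4,
        seed=11,
    )
    return simulate_video(cfg)


@pytest.fixture(scope="session")
def quiet_sim():
    """A video with no apoptosis event (no onset, no ApoBDs)."""
    cfg = SimConfig(
        image_size=(128, 128),
        n_effectors=1,
        n_targets=1,
        onset_frame=None,
        n_frames=6,
        seed=7,
    )
    return simulate_video(cfg)
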