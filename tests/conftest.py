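import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cfmkinetics as cfm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def match_tracks_to_truth(tracks, truth, max_dist_px=2.0):
    """Map each detected track to the nearest ground-truth bead index.

    Returns a list of (track, truth_index) for tracks within ``max_dist_px``
    of a truth position.
    """
    pos = truth.data[["y_px", "x_px"]].to_numpy(float)
    out = []
    for t in tracks:
        d = np.linalg.norm(pos - np.asarray(t.center), axis=1)
        j = int(d.argmin())
        if d[j] <= max_dist_px:
            out.append((t, j))
    return out


@pytest.fixture(scope="session")
def clean_movie_100():
    """100-bead rendered movie with clean (no stuck/slow) exponential decay.

    Contrast-to-noise ratio of 5, the lower edge of the regime the tracker
    is specified for.
    """
    spec = cfm.MovieSpec(
        frame_shape=(512, 512), bead_contrast=50.0, noise_sd=10.0,
        frame_interval=5.0, n_frames=120,
    )
    model = cfm.TetherPopulationModel(
        n_tethers=100, off_rate=0.01, stuck_fraction=0.0, slow_fraction=0.0,
        slow_rate=0.001, duration=1e9, seed=11,
    )
    stack, truth, dataset = cfm.simulate_movie(model, spec)
    return spec, stack, truth, dataset
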