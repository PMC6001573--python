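import numpy as np
import pytest

from gliaquant.motility import SegmentationParams
from gliaquant.synth import MovieSpec, generate_cell_movie


@pytest.fixture(scope="session")
def small_movie():
    """Noise-free 5-cell movie with mixed dynamics, shared across tests."""
    spec = MovieSpec(
        n_cells=5,
        duration_frames=30,
        image_shape=(384, 576),
        translocation_speed_um_min=2.0,
        membrane_change_rate=0.05,
        morph_transition_prob=0.05,
        noise_level=0.0,
        seed=42,
    )
    movie, gt = generate_cell_movie(spec)
    return spec, movie, gt


@pytest.fixture(scope="session")
def noise_free_seg():
    """No smoothing: noise-free rendering segments exactly."""
    return SegmentationParams(smoothing_sigma_px=0.0)


def match_tracks_to_truth(tracks, gt, pixel_size_um):
    """Map each track to the ground-truth cell whose centroid it starts on."""
    mapping = {}
    for t in tracks:
        f0 = int(t.frame_indices[0])
        c0 = np.asarray(t.centroids_um[0]) / pixel_size_um
        sub = gt.table[gt.table.frame == f0]
        d = np.hypot(sub.x_px - c0[0], sub.y_px - c0[1])
        mapping[t.cell_id] = int(sub.iloc[int(np.argmin(d.values))].cell_id)
    return mapping
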