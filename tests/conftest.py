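import numpy as np
import pytest

from trialcal import CellMovieSpec, TrialStructure, generate_cell_movie


from trialcal.synthetic import blob_field


def make_blob_image(h, w, n_blobs, rng, margin=12.0):
    """Seeded field of Gaussian blobs plus the blob centres."""
    return blob_field(h, w, n_blobs, seed=rng, margin=margin)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cell_movie():
    """One default planted-cell trial movie with full ground truth."""
    spec = CellMovieSpec(seed=1)
    stack, mask, truth = generate_cell_movie(spec)
    return spec, stack, mask, truth


@pytest.fixture(scope="session")
def noise_movie():
    """Planted-null movie: pure noise, no cells."""
    spec = CellMovieSpec(n_cells=0, seed=2)
    stack, _, _ = generate_cell_movie(spec)
    return spec, stack


@pytest.fixture()
def short_trial():
    return TrialStructure(n_frames=20, fps=10.0, baseline_frames=np.arange(5))
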