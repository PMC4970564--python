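import numpy as np
import pytest

from alekit.corpus import Corpus, Experiment, Focus
from alekit.grid import make_box_mask


@pytest.fixture
def grid16():
    """16^3 box, 2 mm isotropic, origin at 0."""
    return make_box_mask((16, 16, 16), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture
def grid20():
    """20^3 box, 2 mm isotropic."""
    return make_box_mask((20, 20, 20), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_corpus(rng, grid, n_experiments=10, max_foci=5, metadata_pool=None):
    """A corpus of experiments with uniform in-mask voxel-center foci."""
    mask_idx = grid.mask_indices()
    exps = []
    for i in range(n_experiments):
        n_foci = int(rng.integers(1, max_foci + 1))
        picks = rng.integers(0, len(mask_idx), size=n_foci)
        foci = [Focus.from_xyz(grid.voxel_to_mm(mask_idx[j])) for j in picks]
        metadata = {}
        if metadata_pool:
            for key, values in metadata_pool.items():
                metadata[key] = values[int(rng.integers(0, len(values)))]
        exps.append(
            Experiment(
                id=f"exp-{i:03d}",
                n_subjects=int(rng.integers(5, 40)),
                foci=foci,
                metadata=metadata,
            )
        )
    return Corpus(experiments=exps, space_label="MNI")


@pytest.fixture
def corpus_factory():
    return random_corpus
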