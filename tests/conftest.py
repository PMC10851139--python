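import numpy as np
import pytest

from fedslide.preprocessing import PatchSet, PreprocConfig, preprocess_dataset
from fedslide.synthetic import SiteSpec, generate_multisite_dataset


def make_patchset(patches, slide_id="s", kept=None, sharpness=None):
    """Assemble a PatchSet directly from an array of uint8 patches."""
    patches = np.asarray(patches, dtype=np.uint8)
    n = len(patches)
    return PatchSet(
        slide_id=slide_id,
        patches=patches,
        origins=np.zeros((n, 2), dtype=np.int64),
        sharpness=(
            np.asarray(sharpness, float) if sharpness is not None else np.ones(n)
        ),
        kept=(np.asarray(kept, bool) if kept is not None else np.ones(n, bool)),
    )


def random_patches(rng, n, edge=32):
    return rng.integers(0, 256, size=(n, edge, edge, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def desk_cfg():
    """Desk-scale preprocessing settings used throughout the suite."""
    return PreprocConfig(
        edge_px=32, downscale=1.0, blur_threshold=10.0, min_patches=4
    )


@pytest.fixture(scope="session")
def two_site_shards(desk_cfg):
    """Two small preprocessed sites with balanced labels, for training tests.

    Returns (shards, holdout) where shards maps site id -> list of
    (PatchSet, label) and holdout is a list of (PatchSet, label) pairs
    from the same sites.
    """
    specs = [
        SiteSpec(site_id=1, n_slides=16, melanoma_fraction=0.5,
                 stain_shift=(1.0, 1.0, 1.0)),
        SiteSpec(site_id=2, n_slides=16, melanoma_fraction=0.5,
                 stain_shift=(1.08, 0.96, 1.00)),
    ]
    records = generate_multisite_dataset(specs, seed=11, canvas_px=128,
                                         exact_counts=True)
    included, _, _ = preprocess_dataset(records, desk_cfg)
    shards = {site: [] for site in (1, 2)}
    holdout = []
    for i, (rec, ps) in enumerate(included):
        if i % 4 == 0:
            holdout.append((ps, rec.label_int))
        else:
            shards[rec.site_id].append((ps, rec.label_int))
    return shards, holdout
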