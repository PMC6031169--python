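import numpy as np
import pytest

from layerfusion.preprocess import HumanBlob


def blob_from_mask(mask: np.ndarray, depth: np.ndarray | None = None) -> HumanBlob:
    """Build a HumanBlob directly from a binary grid (tight-cropped)."""
    mask = np.asarray(mask, dtype=np.uint8)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    crop = mask[y0:y1, x0:x1]
    if depth is None:
        depth = np.full(mask.shape, 100, dtype=np.uint8)
    depth_crop = np.where(crop > 0, np.asarray(depth, dtype=np.uint8)[y0:y1, x0:x1], 0)
    bbox = (int(x0), int(y0), int(x1 - x0), int(y1 - y0))
    return HumanBlob(
        raw_bbox=bbox, bbox=bbox, mask=crop,
        depth_profile=depth_crop.astype(np.uint8),
    )


def random_blob(rng: np.random.Generator, height: int = 80, width: int = 50,
                fill: float = 0.4) -> HumanBlob:
    """Random non-empty blob with random depth values on-mask."""
    while True:
        mask = (rng.random((height, width)) < fill).astype(np.uint8)
        if mask.any():
            break
    depth = rng.integers(0, 256, size=mask.shape).astype(np.uint8)
    return blob_from_mask(mask, depth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Shared quiet two-view synthetic corpus, 12 samples per class."""
    from layerfusion.synthetic import SceneConfig, generate_samples

    config = SceneConfig(seed=7)
    return config, generate_samples(config, 12, seed=7)
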