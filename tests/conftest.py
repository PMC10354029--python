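import numpy as np
import pytest

from celltyper import (
    CellTable,
    ClassDef,
    DatasetBundle,
    ImageStack,
    MarkerRule,
    SegmentationMask,
    TissueConfig,
    extract_cell_records,
    generate_tissue,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(pixels, channels=None, fov_id="fov0"):
    pixels = np.asarray(pixels, dtype=float)
    if channels is None:
        channels = [f"ch{i}" for i in range(pixels.shape[0])]
    return ImageStack(fov_id, channels, pixels)


def make_mask(labels, fov_id="fov0"):
    return SegmentationMask(fov_id, np.asarray(labels, dtype=np.int32))


def two_cell_fixture():
    """16x16 FOV with two touching 4x4 square cells and 3 channels."""
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[4:8, 4:8] = 1
    labels[4:8, 8:12] = 2
    rng = np.random.default_rng(0)
    pixels = rng.poisson(2.0, size=(3, 16, 16)).astype(float)
    stack = make_stack(pixels, ["CD4", "CD20", "CD8"])
    mask = make_mask(labels)
    records = extract_cell_records(mask)
    records[0].label = "T"
    records[1].label = "B"
    table = CellTable(records, ["B", "T"])
    return DatasetBundle({"fov0": (stack, mask)}, table)


@pytest.fixture
def two_cell_bundle():
    return two_cell_fixture()


def random_label_image(rng, shape=(32, 32), n_cells=6, radius=4):
    """Random blobby label image for oracle comparisons."""
    labels = np.zeros(shape, dtype=np.int32)
    for cid in range(1, n_cells + 1):
        r = rng.integers(0, shape[0])
        c = rng.integers(0, shape[1])
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        blob = (rr - r) ** 2 + (cc - c) ** 2 <= rng.integers(2, radius + 1) ** 2
        labels[blob & (labels == 0)] = cid
    return labels


def tiny_tissue_config(n_classes=2, n_cells=60, image_shape=(192, 192), **kw):
    """Small nuclear-marker tissue for fast unit tests."""
    channels = [f"nuc{i}" for i in range(n_classes)] + ["dna"]
    classes = [
        ClassDef(
            f"class{i}",
            1.0 / n_classes,
            {
                f"nuc{i}": MarkerRule("nuclear", 3.0),
                "dna": MarkerRule("nuclear", 2.0),
            },
        )
        for i in range(n_classes)
    ]
    return TissueConfig(image_shape=image_shape, n_cells=n_cells,
                        channels=channels, classes=classes, **kw)


@pytest.fixture
def tiny_tissue(rng):
    cfg = tiny_tissue_config()
    return generate_tissue(cfg, rng)
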