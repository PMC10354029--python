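"""Channel normalization and per-cell input tensors.

The classifier input for one cell is a ``(K+2, S, S)`` tensor: crops of the K
protein channels centered on the cell, a binary mask of the cell itself
(channel K), and a binary mask of every other cell in the window (channel
K+1).  The two mask channels are disjoint by construction.

Normalization is optional: raw counts are the default because the Poisson
resampling augmentation assumes count-valued data.  The Anscombe transform
``x -> 2*sqrt(x + 3/8)`` stabilizes Poisson variance; 99th-percentile scaling
divides each channel by its per-FOV 99th percentile and clips to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CellRecord, ImageStack, SegmentationMask

logger = logging.getLogger("celltyper")

__all__ = [
    "CropSpec",
    "CropTensor",
    "build_input_tensor",
    "downsample_stack",
    "normalize_stack",
    "read_tensor_cache",
    "write_tensor_cache",
]


@dataclass(frozen=True)
class CropSpec:
    """Square crop geometry; 60 px suits 0.5 um/px data, 30 px coarser IMC."""

    crop_size_px: int = 60
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.crop_size_px < 4 or self.crop_size_px % 2:
            raise ValueError("crop_size_px must be an even integer >= 4")


@dataclass
class CropTensor:
    """(K+2, S, S) model input for one cell."""

    values: np.ndarray
    channels: list[str]  # K protein names + ["target_mask", "environment_mask"]
    fov_id: str
    cell_id: int

    TARGET = -2  # channel index of the target-cell mask
    ENV = -1  # channel index of the environment mask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(f"values must be (K+2, S, S), got {self.values.shape}")
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("one name per channel required")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0] - 2

    @property
    def size(self) -> int:
        return self.values.shape[1]

    @property
    def protein(self) -> np.ndarray:
        return self.values[:-2]

    @property
    def target_mask(self) -> np.ndarray:
        return self.values[self.TARGET]

    @property
    def environment_mask(self) -> np.ndarray:
        return self.values[self.ENV]

    def validate(self) -> None:
        masks = self.values[-2:]
        if not np.isin(masks, (0.0, 1.0)).all():
            raise ValueError("mask channels must be binary")
        if np.any(masks[0] * masks[1] > 0):
            raise ValueError("target and environment masks must be disjoint")
        if np.any(self.values[:-2] < 0):
            raise ValueError("protein channels must be non-negative")

    def copy(self) -> "CropTensor":
        return CropTensor(self.values.copy(), list(self.channels), self.fov_id, self.cell_id)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_stack(stack: ImageStack, method: str = "none") -> ImageStack:
    """Return a normalized copy of ``stack``.

    ``none`` is the identity; ``anscombe`` applies ``2*sqrt(x + 3/8)`` per
    pixel; ``percentile99`` divides each channel by the 99th percentile of its
    positive pixels in the FOV and clips to [0, 1].  A channel whose 99th
    percentile is zero is
    left unchanged with a logged warning (it is effectively empty).
    """
    if method == "none":
        return ImageStack(stack.fov_id, list(stack.channels), stack.pixels.copy(),
                          stack.pixel_size_um)
    if method == "anscombe":
        out = 2.0 * np.sqrt(stack.pixels + 0.375)
    elif method == "percentile99":
        out = stack.pixels.astype(float).copy()
        for k, name in enumerate(stack.channels):
            support = stack.pixels[k][stack.pixels[k] > 0]
            p99 = float(np.percentile(support, 99)) if support.size else 0.0
            if p99 <= 0:
                logger.warning(
                    "fov %s channel %s: 99th percentile is 0, left unchanged",
                    stack.fov_id, name,
                )
                continue
            out[k] = np.clip(out[k] / p99, 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ImageStack(stack.fov_id, list(stack.channels), out, stack.pixel_size_um)


# ---------------------------------------------------------------------------
# Crop tensors
# ---------------------------------------------------------------------------

def _window_slices(center: int, size: int, limit: int) -> tuple[slice, slice]:
    """Source slice in the image and destination slice in the crop."""
    lo = center - size // 2
    hi = lo + size
    src = slice(max(lo, 0), min(hi, limit))
    dst = slice(src.start - lo, src.stop - lo)
    return src, dst


def build_input_tensor(
    stack: ImageStack,
    mask: SegmentationMask,
    cell: CellRecord,
    spec: CropSpec = CropSpec(),
) -> CropTensor:
    """Build the (K+2, S, S) tensor for ``cell``, padding beyond the FOV edge.

    The window of side S is centered on the centroid rounded to the nearest
    pixel; rows span ``[r - S/2, r + S/2)``.  Out-of-image protein pixels get
    ``spec.pad_value``; mask channels are padded with zeros.
    """
    if stack.shape != mask.shape:
        raise ValueError("stack and mask shapes differ")
    if not np.any(mask.labels == cell.cell_id):
        raise KeyError(f"cell_id {cell.cell_id} absent from mask {mask.fov_id!r}")
    S = spec.crop_size_px
    H, W = mask.shape
    r = int(np.rint(cell.centroid[0]))
    c = int(np.rint(cell.centroid[1]))
    rsrc, rdst = _window_slices(r, S, H)
    csrc, cdst = _window_slices(c, S, W)

    K = stack.n_channels
    values = np.full((K + 2, S, S), 0.0, dtype=np.float32)
    values[:K] = spec.pad_value
    values[:K, rdst, cdst] = stack.pixels[:, rsrc, csrc]
    window = mask.labels[rsrc, csrc]
    values[K, rdst, cdst] = (window == cell.cell_id)
    values[K + 1, rdst, cdst] = (window > 0) & (window != cell.cell_id)
    return CropTensor(values, list(stack.channels) + ["target_mask", "environment_mask"],
                      cell.fov_id, cell.cell_id)


# ---------------------------------------------------------------------------
# Resolution downsampling
# ---------------------------------------------------------------------------

def downsample_stack(
    stack: ImageStack, mask: SegmentationMask, factor: int = 2
) -> tuple[ImageStack, SegmentationMask]:
    """Halve resolution with a 2x2 kernel: counts are block-summed (total
    signal conserved) and the mask takes the majority nonzero id per block
    (ties broken by the smallest id; all-zero blocks stay background)."""
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    H, W = stack.shape
    if H % 2 or W % 2:
        logger.info("fov %s: odd dimension, trailing row/col cropped", stack.fov_id)
    H2, W2 = H // 2, W // 2
    px = stack.pixels[:, : 2 * H2, : 2 * W2]
    summed = px.reshape(stack.n_channels, H2, 2, W2, 2).sum(axis=(2, 4))

    blocks = mask.labels[: 2 * H2, : 2 * W2].reshape(H2, 2, W2, 2)
    cand = blocks.transpose(0, 2, 1, 3).reshape(H2, W2, 4)
    # majority nonzero vote over the 4 candidates, smallest id on ties
    out = np.zeros((H2, W2), dtype=mask.labels.dtype)
    sorted_c = np.sort(cand, axis=2)
    best_count = np.zeros((H2, W2), dtype=np.int8)
    for j in range(4):
        v = sorted_c[:, :, j]
        cnt = (cand == v[:, :, None]).sum(axis=2).astype(np.int8)
        take = (v > 0) & (cnt > best_count)
        out[take] = v[take]
        best_count[take] = cnt[take]
    new_stack = ImageStack(stack.fov_id, list(stack.channels), summed,
                           stack.pixel_size_um * 2)
    return new_stack, SegmentationMask(mask.fov_id, out)


# ---------------------------------------------------------------------------
# Tensor cache
# ---------------------------------------------------------------------------

def write_tensor_cache(tensors: list[CropTensor], directory: str | Path) -> None:
    """One compressed array container per FOV plus an index CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_fov: dict[str, list[CropTensor]] = {}
    for t in tensors:
        by_fov.setdefault(t.fov_id, []).append(t)
    rows = []
    for fov_id, ts in by_fov.items():
        arr = np.stack([t.values for t in ts])
        np.savez_compressed(directory / f"{fov_id}.npz", values=arr,
                            channels=np.array(ts[0].channels))
        for i, t in enumerate(ts):
            rows.append({"fov_id": fov_id, "cell_id": t.cell_id, "offset": i})
    pd.DataFrame(rows, columns=["fov_id", "cell_id", "offset"]).to_csv(
        directory / "index.csv", index=False
    )


def read_tensor_cache(directory: str | Path) -> list[CropTensor]:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv", dtype={"fov_id": str})
    out: list[CropTensor] = []
    for fov_id, grp in index.groupby("fov_id", sort=False):
        with np.load(directory / f"{fov_id}.npz") as z:
            values = z["values"]
            channels = [str(c) for c in z["channels"]]
        for row in grp.itertuples(index=False):
            out.append(CropTensor(values[int(row.offset)], channels, str(fov_id),
                                  int(row.cell_id)))
    return out
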