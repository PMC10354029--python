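"""Training-time augmentations and class-balanced sampling.

Augmentations model the nuisance variation of multiplexed images: arbitrary
tissue orientation (dihedral transforms), segmentation uncertainty (shifting
and resizing the target mask), channel-to-channel registration error
(independent per-channel shifts), and count noise (Gaussian signal averaging
followed by Poisson resampling).  They are applied in a fixed order —
geometry, masks, channel shifts, noise — so seeded runs are reproducible.

Class imbalance (up to 100-fold in tissue) is handled by weighted sampling
with replacement rather than physical duplication: classes equiprobable, or
major lineages equiprobable with classes equiprobable within each lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data_io import CellRecord, CellTable
from .tensorization import CropTensor

__all__ = [
    "AugmentationConfig",
    "SamplerConfig",
    "balanced_sampler",
    "compose_augmentations",
    "poisson_resample",
]


@dataclass
class AugmentationConfig:
    """Flags and magnitudes (pixels) for each augmentation."""

    dihedral: bool = True
    mask_shift: bool = True
    mask_resize: bool = True
    channel_shift: bool = True
    poisson_noise: bool = True
    max_mask_shift_px: int = 5
    max_mask_resize_px: int = 5
    max_channel_shift_px: int = 5
    channel_shift_prob: float = 0.3
    mask_shift_prob: float = 0.5
    mask_resize_prob: float = 0.5
    poisson_prob: float = 0.5
    smoothing_window_px: int = 5
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.channel_shift_prob, self.mask_shift_prob,
                  self.mask_resize_prob, self.poisson_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for m in (self.max_mask_shift_px, self.max_mask_resize_px,
                  self.max_channel_shift_px, self.smoothing_window_px):
            if m < 0:
                raise ValueError("magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(dihedral=False, mask_shift=False, mask_resize=False,
                   channel_shift=False, poisson_noise=False)


# ---------------------------------------------------------------------------
# Individual augmentations
# ---------------------------------------------------------------------------

def _dihedral(arr: np.ndarray, op: int) -> np.ndarray:
    """Apply one of the 8 dihedral transforms to the trailing two axes."""
    out = np.rot90(arr, k=op % 4, axes=(-2, -1))
    if op >= 4:
        out = out[..., ::-1]
    return np.ascontiguousarray(out)


def _shift2d(plane: np.ndarray, dr: int, dc: int, fill: float = 0.0) -> np.ndarray:
    out = np.full_like(plane, fill)
    H, W = plane.shape
    rs_src = slice(max(-dr, 0), min(H - dr, H))
    cs_src = slice(max(-dc, 0), min(W - dc, W))
    rs_dst = slice(rs_src.start + dr, rs_src.stop + dr)
    cs_dst = slice(cs_src.start + dc, cs_src.stop + dc)
    out[rs_dst, cs_dst] = plane[rs_src, cs_src]
    return out


def _disk(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius ** 2


def poisson_resample(
    tensor: CropTensor,
    window_px: int = 5,
    rng: np.random.Generator | None = None,
    sigma: float = 1.0,
) -> CropTensor:
    """Gaussian signal averaging followed by Poisson sampling.

    Each protein channel is replaced by independent Poisson draws whose mean
    is the channel smoothed with a Gaussian kernel truncated to
    ``window_px x window_px``.  Mask channels are untouched.  Requires
    count-valued (non-negative) protein channels.
    """
    rng = np.random.default_rng() if rng is None else rng
    if np.any(tensor.protein < 0):
        raise ValueError("poisson_resample requires non-negative count data")
    out = tensor.copy()
    radius = window_px // 2
    truncate = radius / sigma if sigma > 0 else 0.0
    for k in range(tensor.n_proteins):
        mean = ndimage.gaussian_filter(
            tensor.values[k].astype(float), sigma=sigma, truncate=truncate, mode="constant"
        )
        out.values[k] = rng.poisson(np.maximum(mean, 0.0)).astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def compose_augmentations(
    tensor: CropTensor,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> CropTensor:
    """Apply the augmentation suite to one crop tensor.

    Order: (1) a dihedral transform of all channels jointly; (2) target-mask
    perturbation — integer translation and/or disk dilation-or-erosion, with
    the environment mask rebuilt to stay disjoint; (3) independent integer
    shifts of individual protein channels; (4) Poisson resampling.  With all
    flags disabled the input is returned unchanged.
    """
    out = tensor.copy()
    K = tensor.n_proteins

    if cfg.dihedral:
        op = int(rng.integers(0, 8))
        out.values = _dihedral(out.values, op)

    if cfg.mask_shift and cfg.max_mask_shift_px > 0 and rng.random() < cfg.mask_shift_prob:
        m = cfg.max_mask_shift_px
        dr, dc = (int(v) for v in rng.integers(-m, m + 1, size=2))
        out.values[out.TARGET] = _shift2d(out.values[out.TARGET], dr, dc)

    if cfg.mask_resize and cfg.max_mask_resize_px > 0 and rng.random() < cfg.mask_resize_prob:
        radius = int(rng.integers(1, cfg.max_mask_resize_px + 1))
        grow = bool(rng.integers(0, 2))
        target = out.values[out.TARGET] > 0
        struct = _disk(radius)
        if grow:
            resized = ndimage.binary_dilation(target, structure=struct)
        else:
            resized = ndimage.binary_erosion(target, structure=struct)
            if not resized.any():  # erosion would delete the cell entirely
                resized = target
        out.values[out.TARGET] = resized.astype(np.float32)

    # the target-mask perturbation models segmentation uncertainty of the
    # classified cell; keep the two mask channels disjoint
    overlap = (out.values[out.TARGET] > 0) & (out.values[out.ENV] > 0)
    out.values[out.ENV][overlap] = 0.0

    if cfg.channel_shift and cfg.max_channel_shift_px > 0:
        m = cfg.max_channel_shift_px
        for k in range(K):
            if rng.random() < cfg.channel_shift_prob:
                dr, dc = (int(v) for v in rng.integers(-m, m + 1, size=2))
                out.values[k] = _shift2d(out.values[k], dr, dc)

    if cfg.poisson_noise and rng.random() < cfg.poisson_prob:
        out = poisson_resample(out, cfg.smoothing_window_px, rng, cfg.smoothing_sigma)

    return out


# ---------------------------------------------------------------------------
# Balanced sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """``equal``: classes equiprobable.  ``lineage``: lineages equiprobable,
    classes equiprobable within each lineage (e.g. Myeloid / T cell / tumor /
    B cell / other)."""

    mode: str = "equal"
    lineage_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"equal", "lineage"}:
            raise ValueError(f"unknown sampler mode {self.mode!r}")


def balanced_sampler(
    table: CellTable,
    cfg: SamplerConfig,
    n_draws: int,
    rng: np.random.Generator,
    records: list[CellRecord] | None = None,
) -> list[CellRecord]:
    """Draw ``n_draws`` labeled cells with replacement under the configured
    class weights.  Deterministic given the generator state."""
    pool = table.labeled() if records is None else [r for r in records if r.label is not None]
    by_class: dict[str, list[CellRecord]] = {}
    for rec in pool:
        by_class.setdefault(rec.label, []).append(rec)
    classes = sorted(by_class)
    if not classes:
        raise ValueError("no labeled cells to sample from")
    for cls in table.vocabulary:
        if cls not in by_class:
            raise ValueError(f"class {cls!r} has zero cells in the sampling pool")

    if cfg.mode == "equal":
        class_p = np.full(len(classes), 1.0 / len(classes))
    else:
        missing = [c for c in classes if c not in cfg.lineage_map]
        if missing:
            raise ValueError(f"classes {missing} missing from lineage_map")
        lineages = sorted({cfg.lineage_map[c] for c in classes})
        per_lineage = {
            lin: [c for c in classes if cfg.lineage_map[c] == lin] for lin in lineages
        }
        class_p = np.array(
            [1.0 / len(lineages) / len(per_lineage[cfg.lineage_map[c]]) for c in classes]
        )

    draws_cls = rng.choice(len(classes), size=n_draws, p=class_p)
    out: list[CellRecord] = []
    for ci in draws_cls:
        members = by_class[classes[int(ci)]]
        out.append(members[int(rng.integers(0, len(members)))])
    return out
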