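"""Saliency analysis, spillover simulators, patch overlap and landmark gating.

Guided backpropagation attributes a classification to input pixels: the
gradient of the target-class score is propagated through each rectifier only
where both the forward activation and the incoming gradient are positive,
and the final map keeps positive gradients only.  Summing that map in
concentric disks around the crop center yields a radial profile that
separates nuclear markers (mass concentrated near the center) from
membranous ones (mass reached only near the cell boundary).

The three signal simulators inject synthetic spillover-like signal around a
cell — a Gaussian-located patch, a membrane band with controllable angular
coverage, or a patch anchored on the cell border — to probe whether a
classifier uses the spatial arrangement of signal and not just its total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .baseline import ExpressionMatrix
from .data_io import CellRecord, ImageStack, SegmentationMask
from .ensemble import TrainedModel
from .tensorization import CropTensor

logger = logging.getLogger("celltyper")

__all__ = [
    "RadialProfile",
    "SimulationSpec",
    "gradient_localization",
    "guided_backprop",
    "membrane_sweep",
    "landmark_gate",
    "patch_overlap_analysis",
    "radial_gradient_profile",
    "radius_at_fraction",
    "simulate_signal",
]

MIN_AREA_FOR_RADIAL_PX = 50  # smaller cells carry too little spatial signal
DEFAULT_RADII = tuple(range(1, 18, 2))  # 1..17 px, concentric disks


# ---------------------------------------------------------------------------
# Guided backpropagation
# ---------------------------------------------------------------------------

def guided_backprop(
    model: TrainedModel, tensor: CropTensor, target_class: str | int
) -> np.ndarray:
    """Non-negative (K+2, S, S) saliency map for one (cell, class) pair."""
    if isinstance(target_class, str):
        if target_class not in model.vocabulary:
            raise KeyError(f"class {target_class!r} not in vocabulary")
        target = model.vocabulary.index(target_class)
    else:
        target = int(target_class)
        if not 0 <= target < len(model.vocabulary):
            raise KeyError(f"class index {target} out of range")
    x = tensor.values[None].astype(np.float64)
    logits = model.net.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, target] = 1.0
    grad = model.net.backward(dlogits, guided=True)[0]
    return np.maximum(grad, 0.0)


@dataclass
class RadialProfile:
    """Cumulative normalized gradient mass per channel in concentric disks."""

    channels: list[str]
    radii_px: np.ndarray
    normalized_radii: np.ndarray  # radii / cell radius, sqrt(area / pi)
    profile: np.ndarray  # (n_channels, n_radii), 1.0 at the largest radius

    def channel_profile(self, name: str) -> np.ndarray:
        return self.profile[self.channels.index(name)]


def radial_gradient_profile(
    grad: np.ndarray,
    cell: CellRecord,
    radii: Sequence[int] = DEFAULT_RADII,
    channels: Sequence[str] | None = None,
    min_area_px: int = MIN_AREA_FOR_RADIAL_PX,
) -> RadialProfile | None:
    """Disk-cumulative gradient mass around the crop center, per channel.

    Profiles are normalized to the value at the largest radius; the radius
    axis is normalized by the cell radius ``sqrt(area / pi)``.  Cells smaller
    than ``min_area_px`` are filtered (returns None, logged) since their size
    is too small for spatial analysis.
    """
    if cell.area_px < min_area_px:
        logger.info(
            "cell %s/%d filtered from radial analysis (area %d < %d px)",
            cell.fov_id, cell.cell_id, cell.area_px, min_area_px,
        )
        return None
    grad = np.asarray(grad)
    n_ch, s, _ = grad.shape
    if channels is None:
        channels = [f"channel_{i}" for i in range(n_ch)]
    center = (s - 1) / 2.0
    rr, cc = np.ogrid[:s, :s]
    dist = np.sqrt((rr - center) ** 2 + (cc - center) ** 2)
    radii_arr = np.asarray(radii, dtype=float)
    disks = [dist <= r for r in radii_arr]
    raw = np.stack([[grad[k][d].sum() for d in disks] for k in range(n_ch)])
    largest = raw[:, -1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(largest > 0, raw / largest, np.nan)
    cell_radius = float(np.sqrt(cell.area_px / np.pi))
    return RadialProfile(list(channels), radii_arr, radii_arr / cell_radius, profile)


def radius_at_fraction(
    profile: np.ndarray, normalized_radii: np.ndarray, fraction: float = 0.6
) -> float:
    """Normalized radius at which the cumulative profile first reaches
    ``fraction``, linearly interpolated between profiled radii."""
    profile = np.asarray(profile, dtype=float)
    if np.isnan(profile).any():
        return float("nan")
    idx = np.argmax(profile >= fraction)
    if profile[idx] < fraction:
        return float("nan")
    if idx == 0 or profile[idx] == profile[idx - 1]:
        return float(normalized_radii[idx])
    r0, r1 = normalized_radii[idx - 1], normalized_radii[idx]
    p0, p1 = profile[idx - 1], profile[idx]
    return float(r0 + (fraction - p0) / (p1 - p0) * (r1 - r0))


# ---------------------------------------------------------------------------
# Signal simulators
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Geometry and intensity of one simulated-signal mode.

    ``gaussian_patch``: n_points locations from an isotropic normal (sd_px)
    about the cell center plus ``offset``, each adding a Poisson(lam) count.
    ``membrane``: locations uniform on the band within Chebyshev distance
    ``band_px`` of the cell boundary, restricted to a contiguous arc covering
    ``coverage`` of the boundary; the sampling density over the arc scales as
    1/coverage so the expected total added signal is coverage-independent.
    ``border_patch``: anchor uniform on the cell boundary, locations at
    uniform distance ``distance_range`` from it; requires a minor axis of at
    least ``min_minor_axis_px`` so the patch cannot cover the whole cell.
    """

    mode: str
    channel: str
    lam: float = 1.3
    sd_px: float = 5.0
    band_px: int = 5
    coverage: float = 1.0
    distance_range: tuple[float, float] = (0.0, 6.0)
    offset: tuple[float, float] = (0.0, 0.0)
    n_points: int = 100
    zero_channels: tuple[str, ...] = ()
    crop_size_px: int = 60
    min_minor_axis_px: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in {"gaussian_patch", "membrane", "border_patch"}:
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


_EIGHT = np.ones((3, 3), dtype=bool)


def cell_boundary(mask: SegmentationMask, cell_id: int) -> np.ndarray:
    """Boolean image of cell pixels 8-adjacent to a non-cell pixel."""
    cellpx = mask.labels == cell_id
    interior = ndimage.binary_erosion(cellpx, structure=_EIGHT, border_value=0)
    return cellpx & ~interior


def _zero_crop(pixels: np.ndarray, k: int, cell: CellRecord, size: int) -> None:
    r = int(np.rint(cell.centroid[0]))
    c = int(np.rint(cell.centroid[1]))
    h, w = pixels.shape[1:]
    r0, r1 = max(r - size // 2, 0), min(r - size // 2 + size, h)
    c0, c1 = max(c - size // 2, 0), min(c - size // 2 + size, w)
    pixels[k, r0:r1, c0:c1] = 0


def simulate_signal(
    stack: ImageStack,
    mask: SegmentationMask,
    cell: CellRecord,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> tuple[ImageStack, dict]:
    """Return a modified copy of ``stack`` with simulated signal around ``cell``.

    Pre-existing cognate signal in ``spec.zero_channels`` (and the simulated
    channel itself) is first zeroed within the cell's crop window; simulated
    counts are then added on top of whatever remains elsewhere.
    """
    if spec.channel not in stack.channels:
        raise KeyError(f"channel {spec.channel!r} not in stack")
    pixels = stack.pixels.astype(float).copy()
    h, w = mask.shape
    k = stack.channels.index(spec.channel)
    for name in set(spec.zero_channels) | {spec.channel}:
        _zero_crop(pixels, stack.channels.index(name), cell, spec.crop_size_px)

    info: dict = {"mode": spec.mode, "skipped": False, "n_points": 0, "added_total": 0}
    out_stack = ImageStack(stack.fov_id, list(stack.channels), pixels, stack.pixel_size_um)

    if spec.mode == "border_patch" and cell.minor_axis_px < spec.min_minor_axis_px:
        logger.info(
            "cell %s/%d skipped by border_patch minor-axis filter (%.1f < %.1f px)",
            cell.fov_id, cell.cell_id, cell.minor_axis_px, spec.min_minor_axis_px,
        )
        info["skipped"] = True
        return out_stack, info

    if spec.mode == "gaussian_patch":
        n = spec.n_points
        center = np.asarray(cell.centroid) + np.asarray(spec.offset)
        pts = rng.normal(loc=center, scale=spec.sd_px, size=(n, 2))
    else:
        boundary = np.argwhere(cell_boundary(mask, cell.cell_id))
        if len(boundary) == 0:
            raise ValueError(f"cell {cell.cell_id} has no boundary pixels")
        if spec.mode == "membrane":
            # the nominal sampling rate over the full band is n_points/coverage;
            # restricting to the covered arc leaves n_points effective points,
            # so the expected total added signal is coverage-independent
            n = spec.n_points
            if spec.coverage < 1.0:
                # contiguous arc, parameterized by angle around the centroid
                ang = np.arctan2(
                    boundary[:, 0] - cell.centroid[0], boundary[:, 1] - cell.centroid[1]
                )
                start = rng.uniform(0.0, 2 * np.pi)
                keep = np.mod(ang - start, 2 * np.pi) <= 2 * np.pi * spec.coverage
                if not keep.any():
                    keep[np.argmin(np.mod(ang - start, 2 * np.pi))] = True
                boundary = boundary[keep]
            sel = np.zeros(mask.shape, dtype=bool)
            sel[boundary[:, 0], boundary[:, 1]] = True
            band = ndimage.binary_dilation(
                sel, structure=np.ones((2 * spec.band_px + 1,) * 2, dtype=bool)
            )
            band_px = np.argwhere(band)
            pts = band_px[rng.integers(0, len(band_px), size=n)].astype(float)
        else:  # border_patch
            n = spec.n_points
            anchor = boundary[int(rng.integers(0, len(boundary)))]
            d0, d1 = spec.distance_range
            radii = rng.uniform(d0, d1, size=n)
            theta = rng.uniform(0.0, 2 * np.pi, size=n)
            pts = anchor[None, :] + np.stack(
                [radii * np.sin(theta), radii * np.cos(theta)], axis=1
            )

    rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    counts = rng.poisson(spec.lam, size=n)
    np.add.at(pixels[k], (rows, cols), counts)
    info.update(
        n_points=int(n),
        added_total=int(counts.sum()),
        points=np.stack([rows, cols], axis=1),
    )
    return ImageStack(stack.fov_id, list(stack.channels), pixels, stack.pixel_size_um), info


def _local_view(
    stack: ImageStack, mask: SegmentationMask, cell: CellRecord, half: int
) -> tuple[ImageStack, SegmentationMask, CellRecord]:
    """Window of side 2*half around the cell, with a shifted cell record.

    Simulations and single-cell quantification only touch the cell and its
    immediate surroundings, so working on a local window avoids copying whole
    FOVs.  The window is clamped to the image, keeping the full cell inside
    whenever ``half`` exceeds the cell radius.
    """
    h, w = mask.shape
    r = int(np.rint(cell.centroid[0]))
    c = int(np.rint(cell.centroid[1]))
    r0, c0 = max(r - half, 0), max(c - half, 0)
    r1, c1 = min(r0 + 2 * half, h), min(c0 + 2 * half, w)
    r0, c0 = max(r1 - 2 * half, 0), max(c1 - 2 * half, 0)
    sub_stack = ImageStack(stack.fov_id, list(stack.channels),
                           stack.pixels[:, r0:r1, c0:c1], stack.pixel_size_um)
    sub_mask = SegmentationMask(mask.fov_id, mask.labels[r0:r1, c0:c1])
    br0, bc0, br1, bc1 = cell.bbox
    sub_cell = CellRecord(
        cell.fov_id, cell.cell_id,
        (cell.centroid[0] - r0, cell.centroid[1] - c0),
        cell.area_px,
        (max(br0 - r0, 0), max(bc0 - c0, 0), br1 - r0, bc1 - c0),
        cell.minor_axis_px, cell.major_axis_px, cell.label, cell.merged,
    )
    return sub_stack, sub_mask, sub_cell


def membrane_sweep(
    cnn_models: Sequence[TrainedModel],
    baseline_model,
    bundle,
    cells: Sequence[CellRecord],
    crop_spec,
    source_channel: str,
    target_channel: str,
    target_class: str,
    coverages: Sequence[float] = (1.0, 0.5, 0.25, 0.125),
    n_points_source: int = 200,
    n_points_target: int = 270,
    band_px: int = 2,
    lam: float = 1.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of cells assigned to ``target_class`` versus membrane coverage.

    For each cell, cognate ``source_channel``/``target_channel`` signal is
    removed, the source marker is re-simulated on the full membrane, and the
    target marker is simulated on a contiguous membrane arc covering the given
    fraction — at constant expected total signal, so only the spatial
    concentration varies.  The modified crop is classified by the CNN ensemble
    and, via re-quantified expression, by the tree baseline.
    """
    from .baseline import predict_baseline, quantify_expression
    from .ensemble import ensemble_predict
    from .tensorization import build_input_tensor

    rng = np.random.default_rng(seed)
    half = crop_spec.crop_size_px
    rows = []
    for cov in coverages:
        cnn_hits = 0
        base_hits = 0
        for cell in cells:
            stack, mask = bundle.fovs[cell.fov_id]
            sub_stack, sub_mask, sub_cell = _local_view(stack, mask, cell, half)
            src = SimulationSpec(
                mode="membrane", channel=source_channel, lam=lam, coverage=1.0,
                n_points=n_points_source, band_px=band_px,
                zero_channels=(source_channel, target_channel),
                crop_size_px=crop_spec.crop_size_px,
            )
            sim1, _ = simulate_signal(sub_stack, sub_mask, sub_cell, src, rng)
            tgt = SimulationSpec(
                mode="membrane", channel=target_channel, lam=lam, coverage=cov,
                n_points=n_points_target, band_px=band_px,
                crop_size_px=crop_spec.crop_size_px,
            )
            sim2, _ = simulate_signal(sim1, sub_mask, sub_cell, tgt, rng)
            tensor = build_input_tensor(sim2, sub_mask, sub_cell, crop_spec)
            pred = ensemble_predict(cnn_models, [tensor])[0]
            cnn_hits += pred.predicted_label == target_class
            expr = quantify_expression(sim2, sub_mask)
            bpred = predict_baseline(baseline_model, expr, cells=[sub_cell])[0]
            base_hits += bpred.predicted_label == target_class
        rows.append({
            "coverage": cov,
            "cnn_fraction": cnn_hits / len(cells),
            "baseline_fraction": base_hits / len(cells),
            "n_cells": len(cells),
        })
    return pd.DataFrame(rows)


def gradient_localization(
    model: TrainedModel,
    bundle,
    cells: Sequence[CellRecord],
    crop_spec,
    target_class: str,
    channels: Sequence[str],
    fraction: float = 0.6,
    min_area_px: int = MIN_AREA_FOR_RADIAL_PX,
) -> pd.DataFrame:
    """Mean normalized radius at which each channel's cumulative guided-backprop
    mass reaches ``fraction``, over cells of ``target_class``.

    Nuclear markers reach the threshold at a smaller normalized radius than
    membranous markers of the same class.
    """
    from .tensorization import build_input_tensor

    sums: dict[str, list[float]] = {ch: [] for ch in channels}
    n_used = 0
    for cell in cells:
        stack, mask = bundle.fovs[cell.fov_id]
        tensor = build_input_tensor(stack, mask, cell, crop_spec)
        gmap = guided_backprop(model, tensor, target_class)
        prof = radial_gradient_profile(gmap, cell, channels=tensor.channels,
                                       min_area_px=min_area_px)
        if prof is None:
            continue
        n_used += 1
        for ch in channels:
            r = radius_at_fraction(prof.channel_profile(ch), prof.normalized_radii,
                                   fraction)
            if np.isfinite(r):
                sums[ch].append(r)
    return pd.DataFrame(
        [
            {"channel": ch, "mean_radius_at_fraction": float(np.mean(v)) if v else float("nan"),
             "n_cells": len(v)}
            for ch, v in sums.items()
        ]
    )


# ---------------------------------------------------------------------------
# Patch overlap
# ---------------------------------------------------------------------------

def patch_overlap_analysis(
    channel: np.ndarray,
    mask: SegmentationMask,
    dilation_kernel: int = 3,
    binarize_threshold: float = 0.0,
) -> tuple[dict[int, float], np.ndarray, dict[int, list[int]]]:
    """Signal patches and per-cell overlap fractions.

    The channel is binarized (> threshold), dilated with a
    ``dilation_kernel``-square kernel, and 8-connected components become
    patches.  The overlap fraction of a cell is the share of its pixels with
    positive *undilated* signal; cells touching a dilated patch are assigned
    to it.
    """
    channel = np.asarray(channel)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    binary = channel > binarize_threshold
    dilated = ndimage.binary_dilation(
        binary, structure=np.ones((dilation_kernel,) * 2, dtype=bool)
    )
    patches, _ = ndimage.label(dilated, structure=_EIGHT)
    overlaps: dict[int, float] = {}
    assignments: dict[int, list[int]] = {}
    for cid in mask.cell_ids():
        cellpx = mask.labels == cid
        overlaps[int(cid)] = float(binary[cellpx].sum() / cellpx.sum())
        touched = np.unique(patches[cellpx])
        assignments[int(cid)] = [int(p) for p in touched if p > 0]
    return overlaps, patches, assignments


# ---------------------------------------------------------------------------
# Landmark gating
# ---------------------------------------------------------------------------

@dataclass
class LandmarkOverride:
    """Per-class deviations from the default 20/15 percentile gate."""

    lo_pct: float | None = None
    ignore_others: bool = False


def landmark_gate(
    matrix: ExpressionMatrix,
    class_defs: Mapping[str, Sequence[str]],
    hi_pct: float = 20.0,
    lo_pct: float = 15.0,
    overrides: Mapping[str, LandmarkOverride] | None = None,
) -> pd.Series:
    """Conservative percentile gating for unambiguous "landmark" cells.

    A cell is a landmark of class ``c`` iff every defining protein of ``c``
    exceeds that column's ``hi_pct`` percentile and every other protein is at
    or below its column's ``lo_pct`` percentile.  Overrides allow a per-class
    lo percentile or dropping the other-protein condition entirely.  Cells
    matching zero or multiple classes map to None.
    """
    overrides = dict(overrides or {})
    df = matrix.values
    for cls, proteins in class_defs.items():
        missing = [p for p in proteins if p not in df.columns]
        if missing:
            raise KeyError(f"class {cls!r}: defining proteins {missing} not in matrix")

    hi_thr = df.quantile(hi_pct / 100.0)
    lo_cache: dict[float, pd.Series] = {}

    def lo_thr(pct: float) -> pd.Series:
        if pct not in lo_cache:
            lo_cache[pct] = df.quantile(pct / 100.0)
        return lo_cache[pct]

    hits = pd.DataFrame(index=df.index)
    for cls, proteins in class_defs.items():
        ov = overrides.get(cls, LandmarkOverride())
        ok = np.ones(len(df), dtype=bool)
        for p in proteins:
            ok &= (df[p] > hi_thr[p]).to_numpy()
        if not ov.ignore_others:
            pct = ov.lo_pct if ov.lo_pct is not None else lo_pct
            thr = lo_thr(pct)
            others = [p for p in df.columns if p not in set(proteins)]
            for p in others:
                ok &= (df[p] <= thr[p]).to_numpy()
        hits[cls] = ok

    n_hits = hits.to_numpy().sum(axis=1)
    result = pd.Series([None] * len(df), index=df.index, dtype=object)
    unique = n_hits == 1
    if unique.any():
        cls_names = np.array(list(hits.columns))
        result.iloc[np.flatnonzero(unique)] = cls_names[
            hits.to_numpy()[unique].argmax(axis=1)
        ]
    return result
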