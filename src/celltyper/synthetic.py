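"""Synthetic multiplexed-tissue generator with known ground truth.

The generator emulates the statistical structure the classifier assumes:
count-valued protein channels, nuclear vs. membranous vs. whole-cell marker
localization, densely packed touching cells, signal spillover into the
adjacent pixels of neighboring cells, off-cell noise patches, strong class
imbalance, and occasional merged-cell segmentation errors.  Cells are
ellipses placed by dart-throwing (touching allowed); the nucleus is a
concentric ellipse at half the cell radius and the membrane a 2-px outer
band — the simplest geometry exhibiting the nuclear/membranous distinction.

Everything is reproducible: identical seeds give bitwise-identical images,
masks and tables, and generated bundles are written in the exact on-disk
formats the data layer reads, so fixtures are indistinguishable from real
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data_io import CellTable, DatasetBundle, ImageStack, SegmentationMask, extract_cell_records

__all__ = [
    "ClassDef",
    "MarkerRule",
    "TissueConfig",
    "generate_scenarios",
    "generate_tissue",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class MarkerRule:
    """Expected Poisson counts per pixel in one subcellular compartment."""

    localization: str  # nuclear | membranous | whole_cell
    mean: float

    def __post_init__(self) -> None:
        if self.localization not in {"nuclear", "membranous", "whole_cell"}:
            raise ValueError(f"unknown localization {self.localization!r}")
        if self.mean < 0:
            raise ValueError("mean must be >= 0")


@dataclass(frozen=True)
class ClassDef:
    name: str
    frequency: float
    markers: dict[str, MarkerRule] = field(default_factory=dict)


@dataclass
class TissueConfig:
    """Conditions of one synthetic field of view."""

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 300
    channels: list[str] = field(default_factory=list)
    classes: list[ClassDef] = field(default_factory=list)
    spillover: float = 0.0  # fraction of membranous counts bled into neighbors
    noise_patch_rate: float = 0.0  # expected noise patches per FOV
    noise_patch_points: int = 80
    noise_patch_lam: float = 3.0
    noise_patch_sd: float = 3.0
    noise_boundary_frac: float = 0.0  # patches anchored on cell boundaries (debris)
    merged_rate: float = 0.0  # per-cell probability of fusing into a neighbor
    cell_radius_range: tuple[float, float] = (6.5, 9.5)  # 7-10 um cells at 0.5 um/px
    ellipticity_range: tuple[float, float] = (0.75, 1.0)
    nucleus_scale: float = 0.5
    membrane_width_px: int = 2
    spacing_factor: float = 0.9  # min center distance as a fraction of r_i + r_j
    max_placement_tries: int = 200
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        freqs = [c.frequency for c in self.classes]
        if self.classes and abs(sum(freqs) - 1.0) > 1e-8:
            raise ValueError("class frequencies must sum to 1")
        for rate in (self.spillover, self.merged_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for cls in self.classes:
            unknown = set(cls.markers) - set(self.channels)
            if unknown:
                raise ValueError(f"class {cls.name!r} uses unknown channels {unknown}")


_EIGHT = np.ones((3, 3), dtype=bool)


def _place_centers(cfg: TissueConfig, radii: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    h, w = cfg.image_shape
    centers = np.empty((cfg.n_cells, 2))
    bucket = int(2 * cfg.cell_radius_range[1]) + 1
    grid: dict[tuple[int, int], list[int]] = {}
    for i in range(cfg.n_cells):
        for _ in range(cfg.max_placement_tries):
            r = rng.uniform(radii[i], h - radii[i])
            c = rng.uniform(radii[i], w - radii[i])
            br, bc = int(r // bucket), int(c // bucket)
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    for j in grid.get((br + dr, bc + dc), ()):
                        d = np.hypot(r - centers[j, 0], c - centers[j, 1])
                        if d < cfg.spacing_factor * (radii[i] + radii[j]):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[i] = (r, c)
                grid.setdefault((br, bc), []).append(i)
                break
        else:
            raise ValueError(
                f"cell placement failed after {cfg.max_placement_tries} tries at "
                f"cell {i}; density infeasible for {cfg.image_shape}"
            )
    return centers


def _ellipse_patch(a: float, b: float, phi: float, shape: tuple[int, int],
                   center: tuple[float, float], scale: float = 1.0,
                   pad: int = 0) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Rasterized rotated ellipse as a local boolean patch plus its FOV slices."""
    h, w = shape
    cr, cc = center
    rad = max(a, b) + 1 + pad  # bbox sized for the full cell so compartments align
    r0, r1 = max(int(cr - rad), 0), min(int(cr + rad) + 2, h)
    c0, c1 = max(int(cc - rad), 0), min(int(cc + rad) + 2, w)
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - cr, cc_ - cc
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    inside = (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0
    return inside, (slice(r0, r1), slice(c0, c1))


def generate_tissue(
    cfg: TissueConfig, rng: np.random.Generator, fov_id: str = "fov0"
) -> tuple[ImageStack, SegmentationMask, CellTable]:
    """Generate one FOV: channel stack, segmentation mask and labeled table."""
    if not cfg.classes or not cfg.channels:
        raise ValueError("config must define classes and channels")
    h, w = cfg.image_shape
    n = cfg.n_cells
    freqs = np.array([c.frequency for c in cfg.classes])
    cls_of = rng.choice(len(cfg.classes), size=n, p=freqs)
    radii = rng.uniform(*cfg.cell_radius_range, size=n)
    ratios = rng.uniform(*cfg.ellipticity_range, size=n)
    angles = rng.uniform(0.0, np.pi, size=n)
    centers = _place_centers(cfg, radii, rng)

    labels = np.zeros((h, w), dtype=np.int32)
    compartments: list[dict[str, np.ndarray]] = []
    boxes: list[tuple[slice, slice]] = []
    for i in range(n):
        a, b = radii[i], radii[i] * ratios[i]
        ell, box = _ellipse_patch(a, b, angles[i], (h, w), tuple(centers[i]), pad=2)
        cellpx = ell & (labels[box] == 0)  # first-come on contested pixels
        labels[box][cellpx] = i + 1
        interior = cellpx
        for _ in range(cfg.membrane_width_px):
            interior = ndimage.binary_erosion(interior, structure=_EIGHT, border_value=0)
        nuc_ell, _ = _ellipse_patch(a, b, angles[i], (h, w), tuple(centers[i]),
                                    scale=cfg.nucleus_scale, pad=2)
        compartments.append(
            {"whole_cell": cellpx, "membranous": cellpx & ~interior,
             "nuclear": nuc_ell & cellpx}
        )
        boxes.append(box)

    channel_idx = {name: k for k, name in enumerate(cfg.channels)}
    pixels = np.zeros((len(cfg.channels), h, w), dtype=np.float32)
    membr_totals: list[dict[str, int]] = [dict() for _ in range(n)]
    for i in range(n):
        box = boxes[i]
        for name, rule in cfg.classes[cls_of[i]].markers.items():
            region = compartments[i][rule.localization]
            npx = int(region.sum())
            if npx == 0 or rule.mean == 0:
                continue
            counts = rng.poisson(rule.mean, size=npx)
            pixels[channel_idx[name]][box][region] += counts
            if rule.localization == "membranous":
                membr_totals[i][name] = int(counts.sum())

    if cfg.spillover > 0:
        for i in range(n):
            if not membr_totals[i]:
                continue
            box = boxes[i]
            cellpx = compartments[i]["whole_cell"]
            ring = ndimage.binary_dilation(
                cellpx, structure=np.ones((5, 5), dtype=bool)
            ) & (labels[box] > 0) & (labels[box] != i + 1)
            npx = int(ring.sum())
            if npx == 0:
                continue
            for name, total in membr_totals[i].items():
                lam = cfg.spillover * total / npx
                pixels[channel_idx[name]][box][ring] += rng.poisson(lam, size=npx)

    if cfg.noise_patch_rate > 0:
        for _ in range(int(rng.poisson(cfg.noise_patch_rate))):
            k = int(rng.integers(0, len(cfg.channels)))
            if rng.random() < cfg.noise_boundary_frac:
                # debris adhering to a random cell's membrane
                j = int(rng.integers(0, n))
                phi = rng.uniform(0.0, 2 * np.pi)
                rad = radii[j]
                center = centers[j] + rad * np.array([np.sin(phi), np.cos(phi)])
            else:
                center = rng.uniform([0, 0], [h, w])
            pts = rng.normal(center, cfg.noise_patch_sd, size=(cfg.noise_patch_points, 2))
            rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
            cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
            np.add.at(pixels[k], (rows, cols),
                      rng.poisson(cfg.noise_patch_lam, size=len(rows)))

    merged_into: dict[int, int] = {}
    if cfg.merged_rate > 0:
        merge_draws = rng.random(n)
        for i in range(n):
            if merge_draws[i] >= cfg.merged_rate:
                continue
            # fuse with the nearest cell in reach, bridging any small gap so
            # the merged label is one connected blob, as segmenter errors are
            dists = np.hypot(centers[:, 0] - centers[i, 0],
                             centers[:, 1] - centers[i, 1])
            dists[i] = np.inf
            reach = radii + radii[i] + 4.0
            candidates = [
                int(j) for j in np.flatnonzero(dists <= reach)
                if j + 1 not in merged_into and merged_into.get(j + 1) != i + 1
            ]
            if not candidates:
                continue
            survivor = min(candidates, key=lambda k: dists[k]) + 1
            own = labels == i + 1
            if not own.any() or not (labels == survivor).any():
                continue
            near_i = ndimage.binary_dilation(own, structure=_EIGHT, iterations=3)
            near_j = ndimage.binary_dilation(labels == survivor,
                                             structure=_EIGHT, iterations=3)
            bridge = near_i & near_j & (labels == 0)
            labels[own | bridge] = survivor
            merged_into[i + 1] = survivor

    mask = SegmentationMask(fov_id, labels)
    records = extract_cell_records(mask)
    survivors_flag = set(merged_into.values())
    for rec in records:
        rec.label = cfg.classes[cls_of[rec.cell_id - 1]].name
        rec.merged = rec.cell_id in survivors_flag
    vocab = [c.name for c in cfg.classes]
    stack = ImageStack(fov_id, list(cfg.channels), pixels, cfg.pixel_size_um)
    return stack, mask, CellTable(records, vocab)


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("separable", "spillover", "imbalanced", "merged")

# The spillover scenario mirrors a lymphoid panel: most classes are defined by
# membranous markers that bleed into neighbors, tumor and Treg carry nuclear
# markers, and Treg carries BOTH a nuclear (FoxP3-like) and a membranous
# (CD4-like) marker so nuclear-vs-membranous saliency can be compared within
# one class.  "dna" marks every nucleus and "cd45" every immune membrane.
_SPILL_CHANNELS = ["cd4", "foxp3", "cd20", "cd8", "sox10", "calprotectin",
                   "cd31", "sma", "dna", "cd45"]


def _spillover_classes() -> list[ClassDef]:
    mem, nuc, whole = "membranous", "nuclear", "whole_cell"

    def rules(**kv: tuple[str, float]) -> dict[str, MarkerRule]:
        base = {"dna": MarkerRule(nuc, 2.0)}
        base.update({ch: MarkerRule(loc, mean) for ch, (loc, mean) in kv.items()})
        return base

    imm = ("membranous", 1.0)
    return [
        ClassDef("CD4T", 0.20, rules(cd4=(mem, 2.2), cd45=imm)),
        ClassDef("Treg", 0.10, rules(cd4=(mem, 2.2), foxp3=(nuc, 3.0), cd45=imm)),
        ClassDef("Bcell", 0.15, rules(cd20=(mem, 2.2), cd45=imm)),
        ClassDef("CD8T", 0.15, rules(cd8=(mem, 2.2), cd45=imm)),
        ClassDef("Tumor", 0.15, rules(sox10=(nuc, 3.0))),
        ClassDef("Neutrophil", 0.10, rules(calprotectin=(whole, 1.5), cd45=imm)),
        ClassDef("Endothelial", 0.075, rules(cd31=(mem, 2.2))),
        ClassDef("Stroma", 0.075, rules(sma=(whole, 1.5))),
    ]


_SEP_CHANNELS = [f"nuc{i}" for i in range(8)] + ["dna", "membrane_stain"]


def _separable_classes() -> list[ClassDef]:
    out = []
    for i in range(8):
        markers = {
            f"nuc{i}": MarkerRule("nuclear", 3.0),
            "dna": MarkerRule("nuclear", 2.0),
            "membrane_stain": MarkerRule("membranous", 1.0),
        }
        out.append(ClassDef(f"class{i}", 0.125, markers))
    return out


def _imbalanced_classes() -> list[ClassDef]:
    # rarest : commonest = 1 : 100
    freqs = [0.70, 0.20, 0.093, 0.007]
    return [
        ClassDef(
            f"class{i}", f,
            {
                f"nuc{i}": MarkerRule("nuclear", 3.0),
                "dna": MarkerRule("nuclear", 2.0),
                "membrane_stain": MarkerRule("membranous", 1.0),
            },
        )
        for i, f in enumerate(freqs)
    ]


def scenario_config(name: str, fov_shape: tuple[int, int] = (768, 768),
                    cells_per_fov: int = 850) -> TissueConfig:
    """The TissueConfig behind one named scenario."""
    if name == "separable":
        return TissueConfig(image_shape=fov_shape, n_cells=cells_per_fov,
                            channels=list(_SEP_CHANNELS), classes=_separable_classes())
    if name == "spillover":
        # noise patches are frequent enough that every channel sees
        # cell-overlapping artifact blobs, as real cohorts do
        return TissueConfig(image_shape=fov_shape, n_cells=cells_per_fov,
                            channels=list(_SPILL_CHANNELS), classes=_spillover_classes(),
                            spillover=0.2, noise_patch_rate=120.0,
                            noise_boundary_frac=0.5)
    if name == "imbalanced":
        channels = [f"nuc{i}" for i in range(4)] + ["dna", "membrane_stain"]
        return TissueConfig(image_shape=fov_shape, n_cells=cells_per_fov,
                            channels=channels, classes=_imbalanced_classes())
    if name == "merged":
        return TissueConfig(image_shape=fov_shape, n_cells=cells_per_fov,
                            channels=list(_SEP_CHANNELS), classes=_separable_classes(),
                            merged_rate=0.05)
    raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def generate_scenarios(
    name: str,
    rng: np.random.Generator,
    n_fovs: int = 6,
    n_test_fovs: int = 2,
    fov_shape: tuple[int, int] = (768, 768),
    cells_per_fov: int = 850,
) -> DatasetBundle:
    """A multi-FOV bundle for one named stress scenario with a fixed
    train/test FOV split (the last ``n_test_fovs`` FOVs are held out)."""
    cfg = scenario_config(name, fov_shape, cells_per_fov)
    fovs = {}
    records = []
    vocab: list[str] = []
    for i in range(n_fovs):
        stack, mask, table = generate_tissue(cfg, rng, fov_id=f"fov{i}")
        fovs[stack.fov_id] = (stack, mask)
        records.extend(table.records)
        vocab = table.vocabulary
    fov_ids = [f"fov{i}" for i in range(n_fovs)]
    bundle = DatasetBundle(
        fovs,
        CellTable(records, vocab),
        train_fovs=fov_ids[: n_fovs - n_test_fovs],
        test_fovs=fov_ids[n_fovs - n_test_fovs:],
    )
    return bundle
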