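"""Reading, writing and validation of multiplexed-imaging inputs.

Multiplexed imaging platforms (MIBI-TOF, CODEX, IMC) all reduce to the same
on-disk structure: per field of view (FOV), one count-valued image per
protein, an integer-labeled cell segmentation mask, and a table of expert
cell-type labels.  This module reads those files into validated in-memory
containers, derives per-cell geometric records from the masks, and writes
prediction tables.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; bounding boxes are half-open.
* Channel images are one single-channel TIFF per protein (filename stem =
  protein name) inside a per-FOV directory, or one multichannel OME-TIFF per
  FOV whose channel names come from the OME metadata.
* Segmentation TIFFs must be unsigned (or non-negative signed) integers;
  float masks are rejected, since label images must be exact.
"""

from __future__ import annotations


import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import regionprops

logger = logging.getLogger("celltyper")

__all__ = [
    "CellRecord",
    "CellTable",
    "ConsistencyError",
    "DatasetBundle",
    "ImageStack",
    "Prediction",
    "SegmentationMask",
    "ShapeMismatchError",
    "extract_cell_records",
    "is_border_cell",
    "load_dataset",
    "read_predictions",
    "write_dataset",
    "write_predictions",
]


class ShapeMismatchError(ValueError):
    """Image and mask shapes disagree for a field of view."""


class ConsistencyError(ValueError):
    """Cross-file references (labels vs. masks, duplicate ids) are broken."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """K count-valued protein channel images for one field of view."""

    fov_id: str
    channels: list[str]
    pixels: np.ndarray  # (K, H, W), non-negative
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (K, H, W), got {self.pixels.shape}")
        if len(self.channels) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.pixels.shape[0]} images"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.pixels.shape[0] < 1:
            raise ValueError("need at least one channel")
        if np.any(self.pixels < 0):
            raise ValueError("channel images must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channels.index(name)]

    def subset(self, names: Sequence[str]) -> "ImageStack":
        """Restrict to ``names``, preserving the requested order."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"unknown channels {missing} in fov {self.fov_id!r}")
        idx = [self.channels.index(n) for n in names]
        return ImageStack(self.fov_id, list(names), self.pixels[idx], self.pixel_size_um)


@dataclass
class SegmentationMask:
    """Integer label image: 0 = background, i > 0 = cell i."""

    fov_id: str
    labels: np.ndarray  # (H, W) non-negative integers

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("segmentation mask must be an integer image")
        if self.labels.min(initial=0) < 0:
            raise ValueError("segmentation labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellRecord:
    """Geometry of one segmented cell, plus its optional expert label."""

    fov_id: str
    cell_id: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    minor_axis_px: float
    major_axis_px: float = 0.0
    label: str | None = None
    merged: bool = False  # synthetic ground truth: cell is a fused segmentation error

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        r, c = self.centroid
        r0, c0, r1, c1 = self.bbox
        if not (r0 <= r < r1 and c0 <= c < c1):
            raise ValueError("centroid must lie within bbox")


@dataclass
class CellTable:
    """Per-cell records across FOVs with an ordered label vocabulary."""

    records: list[CellRecord] = field(default_factory=list)
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.fov_id, r.cell_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("(fov_id, cell_id) pairs must be unique")
        seen = {r.label for r in self.records if r.label is not None}
        unknown = seen - set(self.vocabulary)
        if unknown:
            raise ConsistencyError(f"labels {sorted(unknown)} missing from vocabulary")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labeled(self) -> list[CellRecord]:
        return [r for r in self.records if r.label is not None]

    def by_fov(self, fov_id: str) -> list[CellRecord]:
        return [r for r in self.records if r.fov_id == fov_id]

    def get(self, fov_id: str, cell_id: int) -> CellRecord:
        for r in self.records:
            if r.fov_id == fov_id and r.cell_id == cell_id:
                return r
        raise KeyError((fov_id, cell_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fov_id": [r.fov_id for r in self.records],
                "cell_id": [r.cell_id for r in self.records],
                "label": [r.label for r in self.records],
                "area_px": [r.area_px for r in self.records],
                "minor_axis_px": [r.minor_axis_px for r in self.records],
                "merged": [r.merged for r in self.records],
            }
        )


@dataclass
class DatasetBundle:
    """Validated (images, masks, labels) for a set of FOVs."""

    fovs: dict[str, tuple[ImageStack, SegmentationMask]]
    cells: CellTable
    train_fovs: list[str] = field(default_factory=list)
    test_fovs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        channel_lists = {tuple(s.channels) for s, _ in self.fovs.values()}
        if len(channel_lists) > 1:
            raise ConsistencyError("channel lists differ across FOVs")
        for stack, mask in self.fovs.values():
            if stack.shape != mask.shape:
                raise ShapeMismatchError(
                    f"fov {stack.fov_id!r}: image {stack.shape} vs mask {mask.shape}"
                )
        for rec in self.cells:
            if rec.fov_id not in self.fovs:
                raise ConsistencyError(f"cell table references unknown fov {rec.fov_id!r}")

    @property
    def channels(self) -> list[str]:
        stack, _ = next(iter(self.fovs.values()))
        return stack.channels

    @property
    def vocabulary(self) -> list[str]:
        return self.cells.vocabulary

    def stack(self, fov_id: str) -> ImageStack:
        return self.fovs[fov_id][0]

    def mask(self, fov_id: str) -> SegmentationMask:
        return self.fovs[fov_id][1]

    def subset_channels(self, names: Sequence[str]) -> "DatasetBundle":
        fovs = {f: (s.subset(names), m) for f, (s, m) in self.fovs.items()}
        return DatasetBundle(fovs, self.cells, list(self.train_fovs), list(self.test_fovs))

    def split(self) -> tuple["DatasetBundle", "DatasetBundle"]:
        """Return (train, test) bundles following the recorded FOV split."""
        if not self.train_fovs or not self.test_fovs:
            raise ValueError("bundle has no recorded train/test FOV split")

        def _take(fov_ids: list[str]) -> DatasetBundle:
            fovs = {f: self.fovs[f] for f in fov_ids}
            recs = [r for r in self.cells if r.fov_id in fovs]
            return DatasetBundle(fovs, CellTable(recs, list(self.vocabulary)))

        return _take(self.train_fovs), _take(self.test_fovs)


# ---------------------------------------------------------------------------
# Cell records from masks
# ---------------------------------------------------------------------------

def extract_cell_records(mask: SegmentationMask) -> list[CellRecord]:
    """One geometric record per positive id in ``mask``.

    Centroid is the mean of member pixel coordinates, area the member pixel
    count, and the minor/major axes are the ellipse-equivalent full widths
    derived from the eigenvalues of the pixel covariance matrix — the standard
    region-properties convention.
    """
    out: list[CellRecord] = []
    for rp in regionprops(mask.labels):
        r0, c0, r1, c1 = rp.bbox
        out.append(
            CellRecord(
                fov_id=mask.fov_id,
                cell_id=int(rp.label),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                minor_axis_px=float(rp.axis_minor_length),
                major_axis_px=float(rp.axis_major_length),
            )
        )
    out.sort(key=lambda r: r.cell_id)
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_OME_NAME_RE = re.compile(r'Channel[^>]*Name="([^"]+)"')


def _read_channel_dir(fov_dir: Path) -> tuple[list[str], np.ndarray]:
    tiffs = sorted(p for p in fov_dir.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
    if not tiffs:
        raise FileNotFoundError(f"no channel TIFFs in {fov_dir}")
    names = [p.stem for p in tiffs]
    planes = [np.asarray(tifffile.imread(p)) for p in tiffs]
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"fov {fov_dir.name!r}: channel shapes differ: {shapes}")
    return names, np.stack(planes)


def _read_ome_tiff(path: Path) -> tuple[list[str], np.ndarray]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected (C, H, W), got {arr.shape}")
    names = _OME_NAME_RE.findall(desc)
    if len(names) != arr.shape[0]:
        names = [f"channel_{i}" for i in range(arr.shape[0])]
    return names, arr


def _read_mask(path: Path, fov_id: str) -> SegmentationMask:
    arr = np.asarray(tifffile.imread(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"mask {path} is {arr.dtype}; label images must be integer")
    return SegmentationMask(fov_id, arr.astype(np.int32))


def is_border_cell(rec: CellRecord, shape: tuple[int, int]) -> bool:
    """True if the cell's bounding box touches the FOV edge."""
    r0, c0, r1, c1 = rec.bbox
    return r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]


def load_dataset(
    image_dir: str | Path,
    seg_dir: str | Path,
    labels_path: str | Path,
    channel_subset: Sequence[str] | None = None,
    drop_border_cells: bool = False,
) -> DatasetBundle:
    """Read a dataset of per-FOV channel TIFFs (or OME-TIFFs), masks and labels.

    ``image_dir`` holds either one sub-directory per FOV containing one TIFF per
    protein, or one ``<fov>.ome.tif`` per FOV.  ``seg_dir`` holds ``<fov>.tif``
    integer masks.  ``labels_path`` is a CSV with columns fov_id, cell_id, label.
    Cells touching the FOV border are kept by default (their crops are padded);
    ``drop_border_cells`` removes them from the cell table instead.
    """
    image_dir, seg_dir = Path(image_dir), Path(seg_dir)
    labels = pd.read_csv(labels_path, dtype={"fov_id": str})
    required = {"fov_id", "cell_id", "label"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")

    fovs: dict[str, tuple[ImageStack, SegmentationMask]] = {}
    subdirs = sorted(p for p in image_dir.iterdir() if p.is_dir())
    ome = sorted(image_dir.glob("*.ome.tif")) + sorted(image_dir.glob("*.ome.tiff"))
    sources: list[tuple[str, object]] = [(p.name, p) for p in subdirs]
    sources += [(p.name.split(".ome.")[0], p) for p in ome]
    if not sources:
        raise FileNotFoundError(f"no FOV directories or OME-TIFFs under {image_dir}")

    for fov_id, src in sources:
        if isinstance(src, Path) and src.is_dir():
            names, pixels = _read_channel_dir(src)
        else:
            names, pixels = _read_ome_tiff(src)  # type: ignore[arg-type]
        stack = ImageStack(fov_id, names, pixels)
        mask_path = None
        for suffix in (".tif", ".tiff"):
            cand = seg_dir / f"{fov_id}{suffix}"
            if cand.exists():
                mask_path = cand
                break
        if mask_path is None:
            raise FileNotFoundError(f"no segmentation mask for fov {fov_id!r} in {seg_dir}")
        mask = _read_mask(mask_path, fov_id)
        if stack.shape != mask.shape:
            raise ShapeMismatchError(
                f"fov {fov_id!r}: image {stack.shape} vs mask {mask.shape}"
            )
        if channel_subset is not None:
            stack = stack.subset(channel_subset)
        fovs[fov_id] = (stack, mask)

    label_map: dict[tuple[str, int], str] = {}
    for row in labels.itertuples(index=False):
        key = (str(row.fov_id), int(row.cell_id))
        if key in label_map:
            raise ConsistencyError(f"duplicate label row for {key}")
        label_map[key] = str(row.label)

    records: list[CellRecord] = []
    for fov_id, (_, mask) in fovs.items():
        recs = extract_cell_records(mask)
        present = {r.cell_id for r in recs}
        if drop_border_cells:
            recs = [r for r in recs if not is_border_cell(r, mask.shape)]
        for (f, cid), lab in label_map.items():
            if f == fov_id and cid not in present:
                raise ConsistencyError(
                    f"label references cell_id {cid} absent from mask of fov {f!r}"
                )
        for rec in recs:
            rec.label = label_map.get((fov_id, rec.cell_id))
        records.extend(recs)
    for f, cid in label_map:
        if f not in fovs:
            raise ConsistencyError(f"label references unknown fov {f!r}")

    vocabulary = sorted({lab for lab in label_map.values()})
    return DatasetBundle(fovs, CellTable(records, vocabulary))


def write_dataset(bundle: DatasetBundle, image_dir: str | Path, seg_dir: str | Path,
                  labels_path: str | Path) -> None:
    """Write ``bundle`` in the exact format :func:`load_dataset` reads."""
    image_dir, seg_dir = Path(image_dir), Path(seg_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    seg_dir.mkdir(parents=True, exist_ok=True)
    for fov_id, (stack, mask) in bundle.fovs.items():
        fov_dir = image_dir / fov_id
        fov_dir.mkdir(exist_ok=True)
        for name, plane in zip(stack.channels, stack.pixels):
            tifffile.imwrite(fov_dir / f"{name}.tif", plane)
        tifffile.imwrite(seg_dir / f"{fov_id}.tif", mask.labels.astype(np.uint32))
    rows = [
        {"fov_id": r.fov_id, "cell_id": r.cell_id, "label": r.label}
        for r in bundle.cells.labeled()
    ]
    pd.DataFrame(rows, columns=["fov_id", "cell_id", "label"]).to_csv(
        labels_path, index=False
    )


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Ensemble output for one cell.

    ``predicted_label`` is the argmax of the averaged probability vector and
    ``confidence`` its maximum.
    """

    fov_id: str
    cell_id: int
    probabilities: np.ndarray
    vocabulary: list[str]

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.vocabulary),):
            raise ValueError("one probability per vocabulary class required")
        if abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1 within 1e-6")

    @property
    def class_index(self) -> int:
        return int(np.argmax(self.probabilities))  # ties -> lowest index

    @property
    def predicted_label(self) -> str:
        return self.vocabulary[self.class_index]

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())


def write_predictions(preds: Sequence[Prediction], path: str | Path) -> None:
    """CSV with fov_id, cell_id, predicted_label, confidence and prob_<class> columns."""
    if preds:
        vocab = preds[0].vocabulary
        for p in preds:
            if p.vocabulary != vocab:
                raise ConsistencyError("predictions must share one vocabulary")
        keys = [(p.fov_id, p.cell_id) for p in preds]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("duplicate (fov_id, cell_id) in predictions")
    else:
        vocab = []
    cols = ["fov_id", "cell_id", "predicted_label", "confidence"] + [
        f"prob_{c}" for c in vocab
    ]
    rows = []
    for p in preds:
        row = {
            "fov_id": p.fov_id,
            "cell_id": p.cell_id,
            "predicted_label": p.predicted_label,
            "confidence": repr(p.confidence),
        }
        row.update({f"prob_{c}": repr(float(v)) for c, v in zip(vocab, p.probabilities)})
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[Prediction]:
    df = pd.read_csv(path, dtype={"fov_id": str})
    vocab = [c[len("prob_"):] for c in df.columns if c.startswith("prob_")]
    prob_mat = df[[f"prob_{c}" for c in vocab]].to_numpy(dtype=float) if len(df) else None
    out = []
    for i in range(len(df)):
        out.append(
            Prediction(
                str(df["fov_id"].iloc[i]), int(df["cell_id"].iloc[i]), prob_mat[i], vocab
            )
        )
    return out
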