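"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible — per-pixel scans, explicit
loops, breadth-first flood fill — so it shares no code path with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def records_by_pixel_scan(labels: np.ndarray) -> dict[int, dict]:
    """Per-id centroid/area/bbox/axes from an explicit pixel scan."""
    out: dict[int, dict] = {}
    coords: dict[int, list[tuple[int, int]]] = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            v = int(labels[r, c])
            if v > 0:
                coords.setdefault(v, []).append((r, c))
    for cid, pts in coords.items():
        arr = np.array(pts, dtype=float)
        centroid = arr.mean(axis=0)
        rmin, cmin = arr.min(axis=0)
        rmax, cmax = arr.max(axis=0)
        # ellipse-equivalent axes from second central moments
        d = arr - centroid
        cov = d.T @ d / len(arr)
        evals = np.linalg.eigvalsh(cov)
        out[cid] = {
            "centroid": (centroid[0], centroid[1]),
            "area": len(pts),
            "bbox": (int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
            "minor_axis": 4.0 * np.sqrt(max(evals[0], 0.0)),
            "major_axis": 4.0 * np.sqrt(max(evals[1], 0.0)),
        }
    return out


def crop_masks_by_membership(labels: np.ndarray, cell_id: int,
                             center: tuple[int, int], size: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Target/environment windows by testing membership pixel by pixel."""
    target = np.zeros((size, size))
    env = np.zeros((size, size))
    h, w = labels.shape
    r0 = center[0] - size // 2
    c0 = center[1] - size // 2
    for i in range(size):
        for j in range(size):
            r, c = r0 + i, c0 + j
            if 0 <= r < h and 0 <= c < w:
                v = int(labels[r, c])
                if v == cell_id:
                    target[i, j] = 1
                elif v > 0:
                    env[i, j] = 1
    return target, env


def block_majority_vote(labels: np.ndarray) -> np.ndarray:
    """2x2 majority-nonzero downsampling, smallest id on ties."""
    h, w = labels.shape
    out = np.zeros((h // 2, w // 2), dtype=labels.dtype)
    for i in range(h // 2):
        for j in range(w // 2):
            vals = [int(labels[2 * i + a, 2 * j + b]) for a in (0, 1) for b in (0, 1)]
            nz = [v for v in vals if v > 0]
            if not nz:
                continue
            counts: dict[int, int] = {}
            for v in nz:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            out[i, j] = min(v for v, k in counts.items() if k == best)
    return out


def dilate_square(binary: np.ndarray, k: int) -> np.ndarray:
    """Morphological dilation with a k x k square by explicit neighborhood scan."""
    h, w = binary.shape
    half = k // 2
    out = np.zeros_like(binary, dtype=bool)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(r - half, 0), min(r + half + 1, h)
            c0, c1 = max(c - half, 0), min(c + half + 1, w)
            out[r, c] = binary[r0:r1, c0:c1].any()
    return out


def flood_label_8(binary: np.ndarray) -> np.ndarray:
    """8-connected component labeling via breadth-first flood fill."""
    h, w = binary.shape
    lab = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] and lab[r, c] == 0:
                nxt += 1
                q = deque([(r, c)])
                lab[r, c] = nxt
                while q:
                    y, x = q.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w and binary[yy, xx]
                                    and lab[yy, xx] == 0):
                                lab[yy, xx] = nxt
                                q.append((yy, xx))
    return lab


def landmark_scan(values: np.ndarray, columns: list[str],
                  class_defs: dict[str, list[str]], hi_pct: float, lo_pct: float
                  ) -> list[str | None]:
    """Percentile gate evaluated row by row with np.percentile thresholds."""
    hi = {c: np.percentile(values[:, i], hi_pct) for i, c in enumerate(columns)}
    lo = {c: np.percentile(values[:, i], lo_pct) for i, c in enumerate(columns)}
    out: list[str | None] = []
    for row in values:
        matches = []
        for cls, defs in class_defs.items():
            ok = all(row[columns.index(p)] > hi[p] for p in defs)
            ok = ok and all(
                row[columns.index(p)] <= lo[p] for p in columns if p not in defs
            )
            if ok:
                matches.append(cls)
        out.append(matches[0] if len(matches) == 1 else None)
    return out


def metrics_by_counting(y_true: list[str], y_pred: list[str]
                        ) -> dict[str, dict[str, float]]:
    """Per-class recall/precision/F1 from explicit tallies."""
    out: dict[str, dict[str, float]] = {}
    for cls in sorted(set(y_true)):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if tp + fp else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        out[cls] = {"recall": recall, "precision": precision, "f1": f1}
    return out
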