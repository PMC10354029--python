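"""Per-cell expression quantification and the gradient-boosted-tree baseline.

The expression matrix is the classical route to cell typing: per cell and
protein, the channel counts are summed over the cell's pixels, divided by the
cell area, and arcsinh-transformed (``arcsinh(x / cofactor)``, cofactor 1 by
default).  A shallow gradient-boosted tree multi-class model (100 trees of
depth 2) fitted to this matrix is the benchmark the image-based ensemble is
compared against; both emit format-identical prediction lists so every
downstream analysis runs unchanged on either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .data_io import CellRecord, DatasetBundle, ImageStack, Prediction, SegmentationMask

__all__ = [
    "BaselineModel",
    "ExpressionMatrix",
    "fit_baseline",
    "predict_baseline",
    "quantify_bundle",
    "quantify_expression",
]


@dataclass
class ExpressionMatrix:
    """Cells x proteins table of arcsinh-transformed size-normalized expression."""

    values: pd.DataFrame  # MultiIndex (fov_id, cell_id) rows, protein columns
    cofactor: float = 1.0

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate (fov_id, cell_id) rows")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate protein columns")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def row(self, fov_id: str, cell_id: int) -> pd.Series:
        return self.values.loc[(fov_id, cell_id)]

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        if self.cofactor != other.cofactor:
            raise ValueError("cofactors differ")
        return ExpressionMatrix(pd.concat([self.values, other.values]), self.cofactor)


def quantify_expression(
    stack: ImageStack,
    mask: SegmentationMask,
    cofactor: float = 1.0,
) -> ExpressionMatrix:
    """Expression rows for one FOV.

    Per cell and channel: sum of counts over the cell's pixels divided by the
    pixel area, then ``arcsinh(mean / cofactor)``.
    """
    if stack.shape != mask.shape:
        raise ValueError(
            f"fov {stack.fov_id!r}: image {stack.shape} vs mask {mask.shape}"
        )
    ids = mask.cell_ids()
    flat = mask.labels.ravel()
    n_bins = int(flat.max()) + 1 if len(ids) else 1
    areas = np.bincount(flat, minlength=n_bins)
    data = {}
    for k, name in enumerate(stack.channels):
        sums = np.bincount(flat, weights=stack.pixels[k].ravel(), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mean = sums[ids] / areas[ids]
        data[name] = np.arcsinh(mean / cofactor)
    index = pd.MultiIndex.from_arrays(
        [[stack.fov_id] * len(ids), ids.astype(int)], names=["fov_id", "cell_id"]
    )
    return ExpressionMatrix(pd.DataFrame(data, index=index), cofactor)


def quantify_bundle(bundle: DatasetBundle, cofactor: float = 1.0) -> ExpressionMatrix:
    parts = [
        quantify_expression(stack, mask, cofactor)
        for stack, mask in bundle.fovs.values()
    ]
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    return out


@dataclass
class BaselineModel:
    """Fitted 100-tree depth-2 gradient-boosted classifier over the matrix."""

    booster: XGBClassifier
    vocabulary: list[str]
    proteins: list[str]
    n_estimators: int = 100
    max_depth: int = 2


def fit_baseline(
    matrix: ExpressionMatrix,
    labels: dict[tuple[str, int], str] | pd.Series,
    balance: bool = False,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 2,
) -> BaselineModel:
    """Fit the tree baseline on labeled rows of ``matrix``.

    ``balance=True`` applies per-class sample weights inversely proportional
    to class frequency; other tree settings stay at library defaults.
    """
    if not isinstance(labels, pd.Series):
        labels = pd.Series(labels)
    labels = labels.reindex(matrix.values.index).dropna()
    vocab = sorted(labels.unique())
    if len(vocab) < 2:
        raise ValueError("labels must cover at least two classes")
    x = matrix.values.loc[labels.index].to_numpy()
    y = np.array([vocab.index(l) for l in labels])
    weights = None
    if balance:
        counts = np.bincount(y, minlength=len(vocab))
        weights = (len(y) / (len(vocab) * counts))[y]
    booster = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    booster.fit(x, y, sample_weight=weights)
    return BaselineModel(booster, vocab, matrix.proteins, n_estimators, max_depth)


def predict_baseline(
    model: BaselineModel, matrix: ExpressionMatrix,
    cells: Sequence[CellRecord] | None = None,
) -> list[Prediction]:
    """Per-row probability vectors, aligned to the training column schema."""
    missing = [p for p in model.proteins if p not in matrix.values.columns]
    if missing:
        raise KeyError(f"matrix lacks training proteins {missing}")
    values = matrix.values[model.proteins]
    if cells is not None:
        idx = pd.MultiIndex.from_arrays(
            [[c.fov_id for c in cells], [c.cell_id for c in cells]],
            names=["fov_id", "cell_id"],
        )
        values = values.loc[idx]
    probs = model.booster.predict_proba(values.to_numpy())
    probs = probs / probs.sum(axis=1, keepdims=True)
    return [
        Prediction(str(fov), int(cid), probs[i], list(model.vocabulary))
        for i, (fov, cid) in enumerate(values.index)
    ]
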