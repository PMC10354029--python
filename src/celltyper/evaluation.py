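"""Metrics and analyses over prediction lists.

Recall is reported per class and summarized as an unweighted macro mean with
standard deviation (the "88 +/- 7%" style of reporting); micro-averaged
recall equals overall accuracy.  Confidence analyses relate the ensemble's
averaged class probability to per-cell protein expression (Pearson
correlation) and contrast confidence distributions for cells where the
prediction agrees vs. disagrees with the expert label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix

from .augmentation import AugmentationConfig, SamplerConfig
from .baseline import ExpressionMatrix
from .data_io import CellRecord, CellTable, ConsistencyError, DatasetBundle, Prediction
from .ensemble import ModelConfig, ensemble_predict, train_model, build_tensors
from .tensorization import CropSpec

logger = logging.getLogger("celltyper")

__all__ = [
    "EvaluationReport",
    "confidence_analysis",
    "evaluate_predictions",
    "training_curve_experiment",
]

_CUTOFF_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 2)


@dataclass
class EvaluationReport:
    """Confusion matrix, per-class metrics and coverage-vs-cutoff curve."""

    classes: list[str]  # classes with truth support, in vocabulary order
    confusion_raw: pd.DataFrame  # rows = truth, cols = predicted
    confusion_normalized: pd.DataFrame  # rows sum to 1
    per_class: pd.DataFrame  # recall / precision / f1 / support per class
    macro_recall: float
    macro_recall_sd: float
    accuracy: float
    coverage: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "macro_recall": self.macro_recall,
            "macro_recall_sd": self.macro_recall_sd,
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
            "coverage": {str(k): v for k, v in self.coverage.items()},
        }


def evaluate_predictions(
    preds: Sequence[Prediction], truth: CellTable
) -> EvaluationReport:
    """Confusion matrix, per-class recall/precision/F1 and macro summary.

    Classes with zero truth support are reported as absent rather than with
    zero scores.  Every predicted cell must have a truth label.
    """
    if not preds:
        raise ValueError("no predictions to evaluate")
    truth_map = {(r.fov_id, r.cell_id): r.label for r in truth if r.label is not None}
    y_true, y_pred, conf = [], [], []
    for p in preds:
        key = (p.fov_id, p.cell_id)
        if key not in truth_map:
            raise ConsistencyError(f"no truth label for predicted cell {key}")
        y_true.append(truth_map[key])
        y_pred.append(p.predicted_label)
        conf.append(p.confidence)
    vocab = preds[0].vocabulary
    support_classes = [c for c in vocab if c in set(y_true)]
    all_classes = [c for c in vocab if c in set(y_true) | set(y_pred)]

    import warnings

    with warnings.catch_warnings():
        # sklearn warns when only one label is present even with labels= given
        warnings.simplefilter("ignore", UserWarning)
        cm = confusion_matrix(y_true, y_pred, labels=all_classes)
    cm_df = pd.DataFrame(cm, index=all_classes, columns=all_classes)
    cm_df = cm_df.loc[support_classes]  # rows: truth classes with support
    row_sums = cm_df.sum(axis=1).to_numpy()
    cm_norm = cm_df.div(row_sums, axis=0)

    rows = {}
    y_true_a, y_pred_a = np.array(y_true), np.array(y_pred)
    for c in support_classes:
        tp = int(((y_true_a == c) & (y_pred_a == c)).sum())
        fn = int(((y_true_a == c) & (y_pred_a != c)).sum())
        fp = int(((y_true_a != c) & (y_pred_a == c)).sum())
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if tp + fp else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        rows[c] = {"recall": recall, "precision": precision, "f1": f1,
                   "support": tp + fn}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    recalls = per_class["recall"].to_numpy()
    conf_a = np.asarray(conf)
    coverage = {float(c): float((conf_a >= c).mean()) for c in _CUTOFF_GRID}
    return EvaluationReport(
        classes=support_classes,
        confusion_raw=cm_df,
        confusion_normalized=cm_norm,
        per_class=per_class,
        macro_recall=float(recalls.mean()),
        macro_recall_sd=float(recalls.std(ddof=0)),
        accuracy=float((y_true_a == y_pred_a).mean()),
        coverage=coverage,
    )


def confidence_analysis(
    preds: Sequence[Prediction],
    matrix: ExpressionMatrix,
    truth: CellTable | None = None,
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Correlate protein expression with prediction confidence.

    For each (predicted class, protein): Pearson correlation between the
    protein's expression and the class's averaged probability over cells
    predicted as that class; strata with fewer than ``min_cells`` cells are
    reported as NaN.  If ``truth`` is given, also return per-cell confidence
    with an agreement flag (for agree/disagree confidence histograms).
    """
    if not preds:
        raise ValueError("no predictions")
    vocab = preds[0].vocabulary
    index = pd.MultiIndex.from_arrays(
        [[p.fov_id for p in preds], [p.cell_id for p in preds]],
        names=["fov_id", "cell_id"],
    )
    probs = pd.DataFrame(
        np.stack([p.probabilities for p in preds]), index=index, columns=vocab
    )
    pred_cls = pd.Series([p.predicted_label for p in preds], index=index)
    expr = matrix.values.reindex(index)
    if expr.isna().any().any():
        raise ConsistencyError("expression matrix does not cover all predicted cells")

    corr = pd.DataFrame(index=vocab, columns=matrix.proteins, dtype=float)
    for cls in vocab:
        sel = (pred_cls == cls).to_numpy()
        if sel.sum() < min_cells:
            continue
        p_cls = probs.loc[sel, cls].to_numpy()
        for prot in matrix.proteins:
            x = expr.loc[sel, prot].to_numpy()
            if np.std(x) == 0 or np.std(p_cls) == 0:
                continue
            corr.loc[cls, prot] = stats.pearsonr(x, p_cls)[0]

    hist = None
    if truth is not None:
        truth_map = {(r.fov_id, r.cell_id): r.label for r in truth
                     if r.label is not None}
        rows = []
        for p in preds:
            t = truth_map.get((p.fov_id, p.cell_id))
            if t is None:
                continue
            rows.append({"fov_id": p.fov_id, "cell_id": p.cell_id,
                         "confidence": p.confidence,
                         "agree": p.predicted_label == t})
        hist = pd.DataFrame(rows)
    return corr, hist


def training_curve_experiment(
    bundle: DatasetBundle,
    crop: CropSpec,
    aug: AugmentationConfig,
    sampler: SamplerConfig,
    cfg: ModelConfig,
    sizes: Sequence[int] = (100, 250, 500, 1000, 5000),
    replicates: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """F1 versus per-class training-set size, mean +/- sd over replicates.

    For each size, that many cells are sampled per class from the training
    FOVs (independently per replicate) and a model trained on them is scored
    on the test FOVs.  Classes with fewer cells than the requested size use
    all their cells and are flagged so those rows can be excluded from
    cross-size comparisons.
    """
    train, test = bundle.split()
    labeled = train.cells.labeled()
    by_class: dict[str, list[CellRecord]] = {}
    for rec in labeled:
        by_class.setdefault(rec.label, []).append(rec)
    test_cells = test.cells.labeled()
    test_tensors = build_tensors(test, test_cells, crop)

    rows = []
    for size in sizes:
        for rep in range(replicates):
            rng = np.random.default_rng(base_seed + 1000 * rep + size)
            subset: list[CellRecord] = []
            flagged: dict[str, bool] = {}
            for cls in sorted(by_class):
                members = by_class[cls]
                flagged[cls] = len(members) < size
                if flagged[cls]:
                    subset.extend(members)
                else:
                    idx = rng.choice(len(members), size=size, replace=False)
                    subset.extend(members[i] for i in idx)
            sub_bundle = DatasetBundle(
                train.fovs, CellTable(subset, list(bundle.vocabulary))
            )
            model = train_model(sub_bundle, crop, aug, sampler, cfg,
                                seed=base_seed + 1000 * rep + size)
            preds = ensemble_predict([model], test_tensors)
            report = evaluate_predictions(preds, test.cells)
            for cls in report.classes:
                rows.append({
                    "class": cls, "size": size, "replicate": rep,
                    "f1": report.per_class.loc[cls, "f1"],
                    "undersized": flagged.get(cls, False),
                })
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["class", "size", "undersized"])["f1"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "f1_mean", "std": "f1_sd"})
    )
    return summary
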