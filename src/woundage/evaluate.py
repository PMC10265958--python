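"""Validation metrics and workflows: confusion matrices, macro AUC, comparisons.

Internal validation routes every contused study sample through the fitted
tandem and scores the predicted wound-age window against the window containing
the sample's true time label.  External validation does the same for held-out
samples whose labels live only in an answer key.  ``compare_models`` repeats
the tandem-versus-flat comparison over several seeds with shared splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .peaktable import PeakTable
from .tandem import (
    FlatModel,
    GroupScheme,
    NodeModel,
    RouteRecord,
    TandemModel,
    build_tandem,
    default_scheme,
    default_specs,
    flat_baseline,
    predict,
)
from .screen import assemble_panels

__all__ = [
    "EvalReport",
    "evaluate",
    "roc_auc_macro",
    "decision_regions",
    "run_internal_validation",
    "run_external_validation",
    "compare_models",
    "ComparisonResult",
]


@dataclass
class EvalReport:
    """Classification report over the scheme's leaf classes."""

    n: int
    n_correct: int
    accuracy: float
    confusion: pd.DataFrame  # rows: true leaf, columns: predicted leaf
    per_class_recall: pd.Series
    macro_auc: float | None = None
    routes: list[RouteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = int(self.confusion.to_numpy().sum())
        trace = int(np.trace(self.confusion.to_numpy()))
        if total != self.n or trace != self.n_correct:
            raise ValueError("confusion matrix inconsistent with n / n_correct")
        if self.n and abs(self.accuracy - self.n_correct / self.n) > 1e-12:
            raise ValueError("accuracy must equal n_correct / n")


def evaluate(predictions, truth, classes, routes=None) -> EvalReport:
    """Score predicted against true leaf labels over a fixed class order."""
    predictions = [str(p) for p in predictions]
    truth = [str(t) for t in truth]
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    classes = [str(c) for c in classes]
    stray = (set(predictions) | set(truth)) - set(classes)
    if stray:
        raise ValueError(f"label(s) {sorted(stray)} outside the class list {classes}")
    n = len(truth)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, predictions):
        confusion.loc[t, p] += 1
    n_correct = int(np.trace(confusion.to_numpy()))
    row_totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        recall = pd.Series(
            np.where(row_totals > 0, np.diag(confusion) / row_totals.replace(0, 1), np.nan),
            index=classes,
            name="recall",
        )
    return EvalReport(
        n=n,
        n_correct=n_correct,
        accuracy=(n_correct / n) if n else float("nan"),
        confusion=confusion,
        per_class_recall=recall,
        routes=list(routes) if routes else [],
    )


def roc_auc_macro(class_scores: pd.DataFrame, truth) -> float:
    """Macro-averaged one-vs-rest AUC from per-class scores.

    ``class_scores`` has one column per class.  Classes absent from the truth
    are excluded with a warning (their one-vs-rest AUC is undefined).
    """
    truth = [str(t) for t in truth]
    if len(truth) != len(class_scores):
        raise ValueError("truth length must match the score matrix")
    present = set(truth)
    aucs = []
    for cls in class_scores.columns:
        if str(cls) not in present:
            warnings.warn(f"class {cls!r} absent from truth; excluded from macro AUC",
                          stacklevel=2)
            continue
        indicator = np.array([1 if t == str(cls) else 0 for t in truth])
        if indicator.all():
            warnings.warn(f"class {cls!r} is the only class in truth; AUC undefined",
                          stacklevel=2)
            continue
        aucs.append(roc_auc_score(indicator, class_scores[cls].to_numpy()))
    if not aucs:
        raise ValueError("no class with both positive and negative samples")
    return float(np.mean(aucs))


def decision_regions(node: NodeModel, bbox=None, grid_n: int = 200) -> pd.DataFrame:
    """Predicted label on a grid over the node's 2-D latent space.

    ``bbox`` is (xmin, xmax, ymin, ymax); by default the training-score bounding
    box padded by 10%.  Returns a grid_n² row frame with columns ``x, y, label``
    — the data behind a classification-hyperplane plot.
    """
    if bbox is None:
        if node.train_scores is None:
            raise ValueError("node has no stored training scores; pass bbox explicitly")
        xmin, ymin = node.train_scores.min(axis=0)
        xmax, ymax = node.train_scores.max(axis=0)
        pad_x, pad_y = 0.1 * (xmax - xmin), 0.1 * (ymax - ymin)
        bbox = (xmin - pad_x, xmax + pad_x, ymin - pad_y, ymax + pad_y)
    xmin, xmax, ymin, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounding box {bbox}")
    xs = np.linspace(xmin, xmax, grid_n)
    ys = np.linspace(ymin, ymax, grid_n)
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])
    labels = node.classifier.predict(points)
    return pd.DataFrame({"x": points[:, 0], "y": points[:, 1],
                         "label": [str(l) for l in labels]})


def _truth_leaves(table: PeakTable, scheme: GroupScheme) -> list[str]:
    return [scheme.leaf_of(l) for l in table.meta["label"]]


def run_internal_validation(tandem: TandemModel, study_table: PeakTable) -> EvalReport:
    """Re-predict every contused study sample through the full tandem."""
    study = study_table.subset_role("study")
    contused = study.subset_labels(set(tandem.scheme.coarse))
    if contused.n_samples == 0:
        raise ValueError("no contused study samples to validate on")
    preds, routes = predict(tandem, contused)
    truth = _truth_leaves(contused, tandem.scheme)
    return evaluate(preds, truth, tandem.leaves, routes=routes)


def run_external_validation(
    tandem: TandemModel, external_table: PeakTable, key: dict[str, str]
) -> EvalReport:
    """Predict held-out external samples and score against the answer key."""
    external = external_table.subset_role("external")
    if external.n_samples == 0:
        raise ValueError("external table contains no external-role samples")
    missing = [sid for sid in external.sample_ids if sid not in key]
    if missing:
        raise ValueError(f"answer key lacks sample(s) {missing[:5]}")
    preds, routes = predict(tandem, external)
    truth = [tandem.scheme.leaf_of(key[sid]) for sid in external.sample_ids]
    return evaluate(preds, truth, tandem.leaves, routes=routes)


@dataclass
class ComparisonResult:
    """Per-seed and aggregate tandem-versus-flat internal accuracies."""

    per_seed: pd.DataFrame  # index: seed; columns: tandem, LR, SVM, RF, MLP
    scatter: pd.DataFrame  # columns: model, actual, predicted, count

    def medians(self) -> pd.Series:
        return self.per_seed.median(axis=0)


def compare_models(
    study_table: PeakTable,
    scheme: GroupScheme | None = None,
    specs=None,
    seeds=(0,),
    frac: float = 0.7,
) -> ComparisonResult:
    """Internal-validation accuracy of the tandem vs the four flat models.

    For every seed the tandem and the flat models share the screened panels and
    the level-1 split seed, so differences reflect the architecture, not the
    split.  The scatter frame counts (actual leaf, predicted leaf) pairs per
    model, aggregated over seeds — the data behind predicted-vs-actual plots.
    """
    scheme = default_scheme() if scheme is None else scheme
    study = study_table.subset_role("study")
    contused = study.subset_labels(set(scheme.coarse))
    truth = _truth_leaves(contused, scheme)
    panels = assemble_panels(study, scheme)
    rows = []
    counts: dict[tuple[str, str, str], int] = {}

    def _tally(model_name: str, preds) -> None:
        for actual, predicted in zip(truth, preds):
            key = (model_name, actual, predicted)
            counts[key] = counts.get(key, 0) + 1

    for seed in seeds:
        specs_seed = default_specs(seed) if specs is None else specs
        tandem = build_tandem(study, scheme, specs_seed, seed=seed, frac=frac,
                              panels=panels)
        preds, _ = predict(tandem, contused)
        row = {"tandem": float(np.mean(np.asarray(preds) == np.asarray(truth)))}
        _tally("tandem", preds)
        flats = flat_baseline(study, specs_seed, seed=seed, scheme=scheme,
                              frac=frac, panels=panels)
        for kind, model in flats.items():
            fpred = model.predict(contused)
            row[kind] = float(np.mean(np.asarray(fpred) == np.asarray(truth)))
            _tally(kind, fpred)
        rows.append(pd.Series(row, name=seed))
    per_seed = pd.DataFrame(rows)
    per_seed.index.name = "seed"
    scatter = pd.DataFrame(
        [(m, a, p, c) for (m, a, p), c in sorted(counts.items())],
        columns=["model", "actual", "predicted", "count"],
    )
    return ComparisonResult(per_seed=per_seed, scatter=scatter)
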