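"""Two-level tandem classification of wound-age windows.

Level 1 assigns a sample to a coarse post-contusion phase (default: Group I =
4–12 h, Group II = 16–32 h, Group III = 36–48 h) from the union biomarker
panel; the routed level-2 node then assigns the final wound-age window (seven
leaves by default: 4, 8, 12, 16–20, 24–32, 36–40 and 44–48 h) using its own
panel, scaler and PLS-DR reducer.  Each node trains four candidate learners —
logistic regression (L-BFGS), SVM (RBF, C = 1.5), random forest (128 trees)
and a multilayer perceptron ((32, 32) hidden layers, Adam, adaptive learning
rate, ≤ 3000 iterations) — on the 2-D reduced training data and keeps the one
with the best held-out validation accuracy (ties go to the later entry in the
order LR < SVM < RF < MLP, favouring the deeper model).

Control samples contribute to biomarker screening only; they are excluded from
classifier training and validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .peaktable import CONTROL_LABEL, PeakTable
from .prep import (
    ReducerParams,
    ScalerParams,
    plsdr_apply,
    plsdr_fit,
    zscore_apply,
    zscore_fit,
)
from .screen import PanelSet, assemble_panels

__all__ = [
    "GroupScheme",
    "default_scheme",
    "LearnerSpec",
    "default_specs",
    "NodeModel",
    "TandemModel",
    "split_train_val",
    "train_node",
    "build_tandem",
    "predict",
    "flat_baseline",
    "save_bundle",
    "load_bundle",
]

logger = logging.getLogger("woundage")

LEARNER_ORDER = ("LR", "SVM", "RF", "MLP")


# ---------------------------------------------------------------------------
# Grouping scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupScheme:
    """Hierarchical label map: time label → coarse group → leaf class."""

    coarse: dict[str, str]  # time label → coarse group
    fine: dict[str, tuple[str, ...]]  # coarse group → leaf classes (ordered)
    leaf_members: dict[str, tuple[str, ...]]  # leaf → time labels (ordered)

    def __post_init__(self) -> None:
        fine_leaves = [leaf for leaves in self.fine.values() for leaf in leaves]
        if len(fine_leaves) != len(set(fine_leaves)):
            raise ValueError("a leaf class appears under more than one coarse group")
        if set(fine_leaves) != set(self.leaf_members):
            raise ValueError("fine leaves and leaf_members disagree")
        labels_via_leaves = [l for leaf in fine_leaves for l in self.leaf_members[leaf]]
        if len(labels_via_leaves) != len(set(labels_via_leaves)):
            raise ValueError("a time label appears in more than one leaf")
        if set(labels_via_leaves) != set(self.coarse):
            raise ValueError("leaves do not partition the coarse map's time labels")
        for leaf, members in self.leaf_members.items():
            groups = {self.coarse[m] for m in members}
            if len(groups) != 1:
                raise ValueError(f"leaf {leaf!r} spans coarse groups {sorted(groups)}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.fine)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(leaf for group in self.fine for leaf in self.fine[group])

    def coarse_of(self, label: str | int) -> str:
        label = str(label)
        if label not in self.coarse:
            raise KeyError(f"time label {label!r} not in scheme")
        return self.coarse[label]

    def leaf_of(self, label: str | int) -> str:
        label = str(label)
        for leaf, members in self.leaf_members.items():
            if label in members:
                return leaf
        raise KeyError(f"time label {label!r} not in scheme")

    def labels_of_group(self, group: str) -> tuple[str, ...]:
        if group not in self.fine:
            raise KeyError(f"coarse group {group!r} not in scheme")
        return tuple(l for l, g in self.coarse.items() if g == group)

    def to_dict(self) -> dict:
        return {
            "coarse": dict(self.coarse),
            "fine": {g: list(v) for g, v in self.fine.items()},
            "leaf_members": {k: list(v) for k, v in self.leaf_members.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroupScheme":
        return cls(
            coarse={str(k): str(v) for k, v in data["coarse"].items()},
            fine={str(g): tuple(map(str, v)) for g, v in data["fine"].items()},
            leaf_members={str(k): tuple(map(str, v)) for k, v in data["leaf_members"].items()},
        )


def default_scheme() -> GroupScheme:
    """The study's grouping: 3 coarse phases refined into 7 wound-age windows."""
    coarse = {}
    for hour in range(4, 13, 4):
        coarse[str(hour)] = "I"
    for hour in range(16, 33, 4):
        coarse[str(hour)] = "II"
    for hour in range(36, 49, 4):
        coarse[str(hour)] = "III"
    fine = {
        "I": ("4", "8", "12"),
        "II": ("16-20", "24-32"),
        "III": ("36-40", "44-48"),
    }
    leaf_members = {
        "4": ("4",),
        "8": ("8",),
        "12": ("12",),
        "16-20": ("16", "20"),
        "24-32": ("24", "28", "32"),
        "36-40": ("36", "40"),
        "44-48": ("44", "48"),
    }
    return GroupScheme(coarse=coarse, fine=fine, leaf_members=leaf_members)


# ---------------------------------------------------------------------------
# Candidate learners
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearnerSpec:
    """One candidate learner: kind plus the study's fixed hyperparameters."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_ORDER:
            raise ValueError(f"unknown learner kind {self.kind!r}; expected {LEARNER_ORDER}")

    def build(self):
        if self.kind == "LR":
            defaults = dict(solver="lbfgs", max_iter=1000)
            defaults.update(self.params)
            return LogisticRegression(**defaults)
        if self.kind == "SVM":
            defaults = dict(C=1.5, kernel="rbf", decision_function_shape="ovr",
                            random_state=self.seed)
            defaults.update(self.params)
            return SVC(**defaults)
        if self.kind == "RF":
            defaults = dict(n_estimators=128, random_state=self.seed)
            defaults.update(self.params)
            return RandomForestClassifier(**defaults)
        defaults = dict(
            hidden_layer_sizes=(32, 32),
            solver="adam",
            learning_rate="adaptive",
            max_iter=3000,
            random_state=self.seed,
        )
        defaults.update(self.params)
        return MLPClassifier(**defaults)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}


def default_specs(seed: int = 0) -> tuple[LearnerSpec, ...]:
    return tuple(LearnerSpec(kind=k, seed=seed) for k in LEARNER_ORDER)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_val(
    table: PeakTable, frac: float = 0.7, seed: int = 0, by: str = "label"
) -> tuple[PeakTable, PeakTable]:
    """Stratified train/validation split of a peak table by class label.

    Per class, ⌊frac·n⌉ rows (at least 1, never all) go to training; the split
    is disjoint, exhaustive and reproducible for a fixed seed.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = table.meta[by]
    train_ids: list[str] = []
    val_ids: list[str] = []
    for value in pd.unique(labels):
        ids = list(labels.index[labels == value])
        if len(ids) < 2:
            raise ValueError(f"class {value!r} has a single sample; cannot split")
        n_train = int(round(frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in perm[:n_train])
        val_ids.extend(ids[i] for i in perm[n_train:])
    return table.subset_samples(train_ids), table.subset_samples(val_ids)


# ---------------------------------------------------------------------------
# Node training
# ---------------------------------------------------------------------------

@dataclass
class NodeModel:
    """One tandem node: panel → scaler → PLS-DR → selected 2-D classifier."""

    name: str
    panel: tuple[str, ...]
    scaler: ScalerParams
    reducer: ReducerParams
    spec: LearnerSpec
    classifier: object
    classes: tuple[str, ...]
    candidate_accuracies: dict[str, float]
    train_scores: np.ndarray | None = None  # 2-D training coordinates (for plots)

    def reduce(self, table: PeakTable) -> np.ndarray:
        missing = [f for f in self.panel if f not in table.feature_ids]
        if missing:
            raise KeyError(f"sample table lacks panel feature(s): {missing[:5]}")
        logx = table.subset_features(self.panel).log_areas()
        return plsdr_apply(self.reducer, zscore_apply(self.scaler, logx))

    def predict(self, table: PeakTable) -> list[str]:
        if table.n_samples == 0:
            return []
        return [str(c) for c in self.classifier.predict(self.reduce(table))]

    def predict_scores(self, table: PeakTable) -> pd.DataFrame:
        """Per-class scores (probabilities when available) for ROC analysis."""
        coords = self.reduce(table)
        if hasattr(self.classifier, "predict_proba"):
            scores = self.classifier.predict_proba(coords)
        else:
            scores = self.classifier.decision_function(coords)
            if scores.ndim == 1:
                scores = np.column_stack([-scores, scores])
        cols = [str(c) for c in self.classifier.classes_]
        return pd.DataFrame(scores, index=table.sample_ids, columns=cols)


@dataclass
class PassthroughNode:
    """Degenerate level-2 node for a coarse group with a single leaf."""

    name: str
    label: str

    @property
    def classes(self) -> tuple[str, ...]:
        return (self.label,)

    def predict(self, table: PeakTable) -> list[str]:
        return [self.label] * table.n_samples


def train_node(
    train: PeakTable,
    val: PeakTable,
    class_of,
    specs=None,
    name: str = "node",
) -> NodeModel:
    """Train one node: fit panel pipeline on train rows, select by val accuracy.

    ``class_of`` maps a time label to the node's class.  All candidates are
    trained on the same 2-D reduced coordinates; a candidate that fails to
    train is logged and excluded (an error only if all fail).  Ties in
    validation accuracy go to the later (deeper) learner in LR<SVM<RF<MLP order.
    """
    specs = default_specs() if specs is None else list(specs)
    y_train = [str(class_of(l)) for l in train.meta["label"]]
    y_val = [str(class_of(l)) for l in val.meta["label"]]
    if len(set(y_train)) < 2:
        raise ValueError(f"node {name!r}: training rows contain a single class")
    logx_train = train.log_areas()
    scaler = zscore_fit(logx_train, drop_constant=False)
    z_train = zscore_apply(scaler, logx_train)
    reducer = plsdr_fit(z_train, y_train)
    x2_train = plsdr_apply(reducer, z_train)
    z_val = zscore_apply(scaler, val.log_areas())
    x2_val = plsdr_apply(reducer, z_val)

    order = {kind: i for i, kind in enumerate(LEARNER_ORDER)}
    fitted: list[tuple[float, int, LearnerSpec, object]] = []
    accuracies: dict[str, float] = {}
    for spec in specs:
        clf = spec.build()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(x2_train, y_train)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("node %s: learner %s failed to train (%s); excluded",
                           name, spec.kind, exc)
            continue
        acc = float(np.mean(np.asarray(clf.predict(x2_val)) == np.asarray(y_val)))
        accuracies[spec.kind] = acc
        fitted.append((acc, order.get(spec.kind, -1), spec, clf))
    if not fitted:
        raise RuntimeError(f"node {name!r}: every candidate learner failed to train")
    _, _, best_spec, best_clf = max(fitted, key=lambda item: (item[0], item[1]))
    logger.info("node %s: selected %s (val acc %.3f of %s)",
                name, best_spec.kind, accuracies[best_spec.kind], accuracies)
    classes = tuple(sorted(set(y_train) | set(y_val)))
    return NodeModel(
        name=name,
        panel=tuple(train.feature_ids),
        scaler=scaler,
        reducer=reducer,
        spec=best_spec,
        classifier=best_clf,
        classes=classes,
        candidate_accuracies=accuracies,
        train_scores=x2_train,
    )


# ---------------------------------------------------------------------------
# Tandem assembly and prediction
# ---------------------------------------------------------------------------

@dataclass
class TandemModel:
    """Level-1 coarse node plus one level-2 node per coarse group."""

    level1: NodeModel | PassthroughNode
    level2: dict[str, NodeModel | PassthroughNode]
    scheme: GroupScheme
    panels: PanelSet
    seed: int = 0

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.scheme.leaves

    def __post_init__(self) -> None:
        for group, leaves in self.scheme.fine.items():
            if group not in self.level2:
                raise ValueError(f"missing level-2 node for coarse group {group!r}")
            node_classes = set(self.level2[group].classes)
            if not node_classes <= set(leaves):
                raise ValueError(
                    f"level-2 node {group!r} predicts {sorted(node_classes)} "
                    f"outside its leaves {leaves}"
                )


def build_tandem(
    study_table: PeakTable,
    scheme: GroupScheme | None = None,
    specs=None,
    seed: int = 0,
    frac: float = 0.7,
    panels: PanelSet | None = None,
    vip_thr: float = 1.0,
    q_thr: float = 0.05,
) -> TandemModel:
    """Screen panels, then train the level-1 and level-2 nodes.

    Panels are screened from the full study table (contused groups vs control);
    control rows are then dropped and each node splits its own samples 70/30
    (stratified by its class) before training.  A coarse group with a single
    leaf gets a passthrough node.
    """
    scheme = default_scheme() if scheme is None else scheme
    specs = default_specs(seed) if specs is None else specs
    study = study_table.subset_role("study")
    if panels is None:
        panels = assemble_panels(study, scheme, vip_thr=vip_thr, q_thr=q_thr)
    contused = study.subset_labels(set(scheme.coarse))

    if len(scheme.groups) == 1:
        # degenerate scheme: nothing to discriminate at level 1
        level1: NodeModel | PassthroughNode = PassthroughNode(
            name="level1", label=scheme.groups[0]
        )
    else:
        level1_table = contused.subset_features(panels.union)
        train1, val1 = split_train_val(level1_table, frac=frac, seed=seed)
        # level-1 split is stratified by time label so every leaf is represented;
        # classes for training are the coarse groups
        level1 = train_node(train1, val1, scheme.coarse_of, specs, name="level1")

    level2: dict[str, NodeModel | PassthroughNode] = {}
    for g_idx, (group, leaves) in enumerate(scheme.fine.items()):
        if len(leaves) == 1:
            level2[group] = PassthroughNode(name=f"level2/{group}", label=leaves[0])
            continue
        group_rows = contused.subset_labels(scheme.labels_of_group(group))
        node_table = group_rows.subset_features(panels.per_node[group])
        train_g, val_g = split_train_val(node_table, frac=frac, seed=seed + 1 + g_idx)
        level2[group] = train_node(
            train_g, val_g, scheme.leaf_of, specs, name=f"level2/{group}"
        )
    return TandemModel(level1=level1, level2=level2, scheme=scheme, panels=panels, seed=seed)


@dataclass(frozen=True)
class RouteRecord:
    sample_id: str
    coarse: str
    leaf: str


def predict(tandem: TandemModel, samples: PeakTable) -> tuple[list[str], list[RouteRecord]]:
    """Route samples through the tandem: coarse prediction, then the group's node.

    The predicted leaf always belongs to the predicted coarse group (routing
    consistency is structural: each level-2 node only knows its own leaves).
    """
    if samples.n_samples == 0:
        return [], []
    coarse_pred = tandem.level1.predict(samples)
    leaf_pred: dict[str, str] = {}
    routes: dict[str, RouteRecord] = {}
    ids = samples.sample_ids
    for group in tandem.scheme.groups:
        routed_ids = [sid for sid, c in zip(ids, coarse_pred) if c == group]
        if not routed_ids:
            continue
        node = tandem.level2[group]
        leaves = node.predict(samples.subset_samples(routed_ids))
        for sid, leaf in zip(routed_ids, leaves):
            leaf_pred[sid] = leaf
            routes[sid] = RouteRecord(sample_id=sid, coarse=group, leaf=leaf)
    ordered = [leaf_pred[sid] for sid in ids]
    return ordered, [routes[sid] for sid in ids]


# ---------------------------------------------------------------------------
# Flat (single-stage) baselines
# ---------------------------------------------------------------------------

@dataclass
class FlatModel:
    """Single-stage 7-leaf classifier sharing the tandem's union panel and split."""

    node: NodeModel
    kind: str

    def predict(self, samples: PeakTable) -> list[str]:
        return self.node.predict(samples)


def flat_baseline(
    study_table: PeakTable,
    specs=None,
    seed: int = 0,
    scheme: GroupScheme | None = None,
    frac: float = 0.7,
    panels: PanelSet | None = None,
) -> dict[str, FlatModel]:
    """Train one-stage leaf classifiers on the union panel, one per learner.

    Uses the same union panel and the same split seed as the tandem's level-1
    node, so comparisons are split-for-split fair.  All four learners share one
    scaler and PLS-DR reduction (fitted on the training rows against the leaf
    encoding) and each is trained on the same 2-D data.
    """
    scheme = default_scheme() if scheme is None else scheme
    specs = default_specs(seed) if specs is None else list(specs)
    study = study_table.subset_role("study")
    if panels is None:
        panels = assemble_panels(study, scheme)
    contused = study.subset_labels(set(scheme.coarse))
    table = contused.subset_features(panels.union)
    train, val = split_train_val(table, frac=frac, seed=seed)
    models: dict[str, FlatModel] = {}
    for spec in specs:
        node = train_node(train, val, scheme.leaf_of, [spec], name=f"flat/{spec.kind}")
        models[spec.kind] = FlatModel(node=node, kind=spec.kind)
    return models


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

def _save_node(node: NodeModel | PassthroughNode, directory: Path) -> dict:
    if isinstance(node, PassthroughNode):
        return {"type": "passthrough", "label": node.label, "name": node.name}
    directory.mkdir(parents=True, exist_ok=True)
    node.scaler.to_frame().to_csv(directory / "scaler.csv")
    np.savetxt(directory / "rotation.csv", node.reducer.rotation, delimiter=",")
    np.savetxt(directory / "x_mean.csv", node.reducer.x_mean, delimiter=",")
    joblib.dump(node.classifier, directory / "classifier.joblib")
    return {
        "type": "node",
        "name": node.name,
        "panel": list(node.panel),
        "classes": list(node.classes),
        "spec": node.spec.to_dict(),
        "candidate_accuracies": {k: float(v) for k, v in node.candidate_accuracies.items()},
        "reducer_classes": list(node.reducer.classes),
        "dropped_features": list(node.scaler.dropped),
    }


def _load_node(entry: dict, directory: Path) -> NodeModel | PassthroughNode:
    if entry["type"] == "passthrough":
        return PassthroughNode(name=entry["name"], label=entry["label"])
    scaler_frame = pd.read_csv(directory / "scaler.csv", index_col=0)
    scaler = ScalerParams.from_frame(scaler_frame, dropped=entry.get("dropped_features", ()))
    rotation = np.loadtxt(directory / "rotation.csv", delimiter=",").reshape(-1, 2)
    x_mean = np.loadtxt(directory / "x_mean.csv", delimiter=",").ravel()
    reducer = ReducerParams(
        x_mean=x_mean,
        rotation=rotation,
        feature_ids=tuple(scaler_frame.index),
        classes=tuple(entry["reducer_classes"]),
    )
    spec = LearnerSpec(**entry["spec"])
    classifier = joblib.load(directory / "classifier.joblib")
    return NodeModel(
        name=entry["name"],
        panel=tuple(entry["panel"]),
        scaler=scaler,
        reducer=reducer,
        spec=spec,
        classifier=classifier,
        classes=tuple(entry["classes"]),
        candidate_accuracies=dict(entry["candidate_accuracies"]),
    )


def save_bundle(tandem: TandemModel, directory: str | Path) -> None:
    """Serialize a fitted tandem to a directory (YAML manifest + per-node files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scheme": tandem.scheme.to_dict(),
        "seed": tandem.seed,
        "panels": {
            "union": list(tandem.panels.union),
            "per_node": {g: list(v) for g, v in tandem.panels.per_node.items()},
            "per_group_counts": dict(tandem.panels.per_group_counts),
        },
        "level1": _save_node(tandem.level1, directory / "level1"),
        "level2": {},
    }
    for group, node in tandem.level2.items():
        manifest["level2"][group] = _save_node(node, directory / f"level2_{group}")
    with open(directory / "manifest.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=False)


def load_bundle(directory: str | Path) -> TandemModel:
    """Load a tandem bundle written by :func:`save_bundle`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml", encoding="utf-8") as handle:
        manifest = yaml.safe_load(handle)
    scheme = GroupScheme.from_dict(manifest["scheme"])
    level1 = _load_node(manifest["level1"], directory / "level1")
    level2 = {
        group: _load_node(entry, directory / f"level2_{group}")
        for group, entry in manifest["level2"].items()
    }
    panels = PanelSet(
        union=tuple(manifest["panels"]["union"]),
        per_node={g: tuple(v) for g, v in manifest["panels"]["per_node"].items()},
        per_group_counts=dict(manifest["panels"]["per_group_counts"]),
    )
    return TandemModel(level1=level1, level2=level2, scheme=scheme,
                       panels=panels, seed=manifest["seed"])
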