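"""Differential-feature screening and panel assembly.

A feature is a differential-metabolite candidate when it satisfies both
VIP > 1 in a two-class OPLS-DA of the case group against control **and**
Benjamini–Hochberg FDR-adjusted P < 0.05 from a feature-wise two-sided Welch
t-test on log areas.  Panels are assembled hierarchically: the first-level
panel is the union of the per-coarse-group screens against control; each
second-level node panel re-screens its own coarse group's samples against
control restricted to that union.  Screens only ever see study rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chemometrics import opls_fit
from .peaktable import CONTROL_LABEL, PeakTable

__all__ = [
    "univariate_p",
    "bh_adjust",
    "screen_features",
    "PanelSet",
    "assemble_panels",
    "hcluster_metabolites",
]


def univariate_p(table: PeakTable, group_labels_a, group_labels_b) -> pd.Series:
    """Two-sided Welch t-test per feature on log-transformed areas.

    ``group_labels_a`` / ``group_labels_b`` select study rows by their time
    label.  Identical groups (zero pooled variance, equal means) get p = 1.
    """
    study = table.subset_role("study")
    a = study.subset_labels(_as_label_set(group_labels_a)).log_areas()
    b = study.subset_labels(_as_label_set(group_labels_b)).log_areas()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples for a Welch t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=False, axis=0)
    # zero-variance columns: p = 1 when the means agree, ~0 when they differ
    nan = ~np.isfinite(p)
    if nan.any():
        same = np.isclose(a.mean(axis=0).to_numpy()[nan], b.mean(axis=0).to_numpy()[nan])
        p[nan] = np.where(same, 1.0, 0.0)
    return pd.Series(p, index=study.feature_ids, name="p")


def bh_adjust(p) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up q-values; order-preserving in p-rank."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def _as_label_set(labels) -> set[str]:
    if isinstance(labels, (str, int)):
        labels = [labels]
    return {str(l) for l in labels}


def screen_features(
    table: PeakTable,
    case_labels,
    control_label: str = CONTROL_LABEL,
    vip_thr: float = 1.0,
    q_thr: float = 0.05,
    a_orth: int = 1,
) -> pd.DataFrame:
    """Screen for differential features: case group(s) pooled vs control.

    Returns one row per feature with columns ``vip, p, q, selected, direction``;
    ``selected`` is the conjunction VIP > vip_thr and q < q_thr, ``direction``
    the sign of the case-minus-control log-mean difference.
    """
    case = _as_label_set(case_labels)
    study = table.subset_role("study")
    present = set(study.meta["label"])
    if control_label not in present:
        raise ValueError(f"control label {control_label!r} absent from study rows")
    missing = case - present
    if missing:
        raise ValueError(f"case label(s) {sorted(missing)} absent from study rows")
    two_class = study.subset_labels(case | {control_label})
    logx = two_class.log_areas()
    binary = ["case" if l in case else "control" for l in two_class.meta["label"]]
    model = opls_fit(logx.to_numpy(float), binary, a_pred=1, a_orth=a_orth)
    vip = pd.Series(model.vip_, index=two_class.feature_ids, name="vip")
    p = univariate_p(table, case, [control_label])
    q = bh_adjust(p)
    mean_case = logx.loc[[b == "case" for b in binary]].mean(axis=0)
    mean_ctrl = logx.loc[[b == "control" for b in binary]].mean(axis=0)
    direction = np.sign(mean_case - mean_ctrl).astype(int)
    out = pd.DataFrame({"vip": vip, "p": p, "q": q, "direction": direction})
    out["selected"] = (out["vip"] > vip_thr) & (out["q"] < q_thr)
    return out[["vip", "p", "q", "selected", "direction"]]


@dataclass(frozen=True)
class PanelSet:
    """First-level (union) panel and the per-coarse-group node panels."""

    union: tuple[str, ...]
    per_node: dict[str, tuple[str, ...]]
    per_group_counts: dict[str, int]


def assemble_panels(
    study_table: PeakTable,
    scheme,
    control_label: str = CONTROL_LABEL,
    vip_thr: float = 1.0,
    q_thr: float = 0.05,
) -> PanelSet:
    """Assemble the hierarchical feature panels used by the tandem classifier.

    The first-level panel is the union of the per-coarse-group screens against
    control; each node panel re-screens the group's samples against control on
    the union features only.  Every node panel is a subset of the union.
    Raises when any screen comes back empty.
    """
    group_selected: dict[str, list[str]] = {}
    for group, leaves in scheme.fine.items():
        labels = scheme.labels_of_group(group)
        result = screen_features(study_table, labels, control_label, vip_thr, q_thr)
        chosen = result.index[result["selected"]].tolist()
        if not chosen:
            raise ValueError(
                f"screen for coarse group {group!r} selected no features; "
                "increase the effect size or relax thresholds"
            )
        group_selected[group] = chosen
    union: list[str] = []
    seen: set[str] = set()
    for feat in study_table.feature_ids:  # keep table order
        if feat in seen:
            continue
        if any(feat in sel for sel in group_selected.values()):
            union.append(feat)
            seen.add(feat)
    per_node: dict[str, tuple[str, ...]] = {}
    restricted = study_table.subset_features(union)
    for group, leaves in scheme.fine.items():
        if len(leaves) <= 1:
            per_node[group] = tuple(f for f in union if f in group_selected[group])
            continue
        labels = scheme.labels_of_group(group)
        result = screen_features(restricted, labels, control_label, vip_thr, q_thr)
        chosen = tuple(result.index[result["selected"]])
        if not chosen:
            raise ValueError(
                f"second-level screen for group {group!r} selected no features"
            )
        per_node[group] = chosen
    return PanelSet(
        union=tuple(union),
        per_node=per_node,
        per_group_counts={g: len(sel) for g, sel in group_selected.items()},
    )


def hcluster_metabolites(group_mean_matrix: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Agglomerative (Ward, Euclidean) clustering of metabolite temporal profiles.

    Rows are metabolites, columns group-mean levels.  Each row is z-scored
    (population SD; constant rows become zeros) before clustering — the usual
    heatmap convention.  Returns ``(leaf order, SciPy linkage matrix)``;
    deterministic, with SciPy's index-order tie-breaking.
    """
    from scipy.cluster import hierarchy

    if len(group_mean_matrix) < 2:
        raise ValueError("need at least 2 metabolites to cluster")
    values = group_mean_matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    linkage = hierarchy.linkage(z, method="ward", metric="euclidean")
    order = hierarchy.leaves_list(linkage).tolist()
    leaves = [group_mean_matrix.index[i] for i in order]
    return leaves, linkage
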