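"""Synthetic peak tables emulating a time-resolved muscle-contusion study.

The generator reproduces the statistical design the downstream analysis assumes:
a control group plus twelve post-contusion time points (4, 8, …, 48 h; n = 9
each, i.e. 117 study samples), pooled quality-control injections, and a small
set of externally generated test samples with hidden labels.

Temporal structure is three-phased — early (4–12 h), intermediate (16–32 h) and
late (36–48 h) — with weaker within-phase sub-structure, matching the coarse
grouping the classifier is built on.  Each panel metabolite follows one of four
trajectory archetypes (early-peak, mid-peak, late-rise, monotone-fall) cycled by
panel position; archetype phase levels are chosen so that, at the default phase
gap, any two time points in different phases differ more in log-mean than any
two points within one phase.  Peak areas are log-normal (positive, heavy-tailed
multiplicative noise); background features are label-independent so the
biomarker screen has a true-negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import load_panel
from .peaktable import CONTROL_LABEL, PeakTable

__all__ = [
    "SyntheticConfig",
    "DEFAULT_TIMEPOINTS",
    "trajectory_mean",
    "generate_study",
    "add_qc",
    "generate_external",
]

DEFAULT_TIMEPOINTS: tuple[int, ...] = tuple(range(4, 49, 4))

# Log-scale level of each archetype in the three phases, in units of one
# within-phase step.  The smallest between-phase level gap across archetypes is
# 0.35, against a maximum within-phase spread of 0.5 (see trajectory_mean), so
# between-phase contrasts dominate whenever phase_gap > 0.5/0.35 ≈ 1.43.
_ARCHETYPE_LEVELS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.4, 0.0),  # early-peak
    (0.2, 1.0, 0.55),  # mid-peak
    (0.0, 0.45, 1.0),  # late-rise
    (-0.3, -0.65, -1.0),  # monotone-fall
)
_ARCHETYPE_DIRECTION: tuple[float, ...] = (1.0, -1.0, 1.0, -1.0)
ARCHETYPE_NAMES: tuple[str, ...] = ("early-peak", "mid-peak", "late-rise", "monotone-fall")
_N_PHASES = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 12 contusion time points plus control,
    9 replicates per group, pooled QC injections, and a panel of 43 informative
    metabolites on top of label-independent background features.
    """

    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_per_group: int = 9
    n_background: int = 500
    effect_scale: float = 1.0
    within_sd: float = 0.25
    phase_gap: float = 3.0
    qc_count: int = 12
    seed: int = 0
    baseline_log_area: float = 10.0
    phase_breaks: tuple[int, int] = (12, 32)  # hour ≤ first → phase 0, ≤ second → 1

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be ≥ 1")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be ≥ 0")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        if self.phase_gap <= 1:
            raise ValueError("phase_gap must be > 1")
        if self.n_background < 0:
            raise ValueError("n_background must be ≥ 0")
        if not self.timepoints or list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be a non-empty increasing sequence")

    def phase_of(self, hour: int) -> int:
        if hour <= self.phase_breaks[0]:
            return 0
        if hour <= self.phase_breaks[1]:
            return 1
        return 2

    @property
    def labels(self) -> tuple[str, ...]:
        return (CONTROL_LABEL,) + tuple(str(t) for t in self.timepoints)


def _panel_feature_names() -> list[str]:
    return [rec.name for rec in load_panel()]


def _background_names(n: int) -> list[str]:
    width = max(4, len(str(max(n, 1))))
    return [f"bg{idx:0{width}d}" for idx in range(1, n + 1)]


def feature_names(config: SyntheticConfig) -> list[str]:
    """Panel metabolite names first, then background feature tags."""
    return _panel_feature_names() + _background_names(config.n_background)


def _within_position(hour: int, config: SyntheticConfig) -> float:
    """Position of ``hour`` inside its phase, scaled to [-0.5, 0.5]."""
    phase = config.phase_of(hour)
    members = [t for t in config.timepoints if config.phase_of(t) == phase]
    if len(members) == 1:
        return 0.0
    rank = members.index(hour)
    return rank / (len(members) - 1) - 0.5


def trajectory_mean(metabolite_index: int, label: str | int, config: SyntheticConfig) -> float:
    """Deterministic log-area mean of one panel metabolite at one group label.

    Control samples sit at the baseline.  For contusion time points the mean is
    baseline + effect_scale × (phase_gap × archetype phase level + within-phase
    offset).  The within-phase offset ramps linearly across one phase with
    amplitude 0.5 and archetype-dependent direction, and each metabolite carries
    it in a single phase only (cycled by panel position): fine temporal detail
    for different phases lives in different metabolites, which is what makes a
    phase-specific second-level panel more informative than one global
    projection.
    """
    if metabolite_index < 0:
        raise ValueError("metabolite_index must be ≥ 0")
    label = str(label)
    if label == CONTROL_LABEL:
        return config.baseline_log_area
    try:
        hour = int(label)
    except ValueError:
        raise ValueError(f"unknown group label {label!r}") from None
    if hour not in config.timepoints:
        raise ValueError(f"label {label!r} is not a configured timepoint")
    arch = metabolite_index % len(_ARCHETYPE_LEVELS)
    phase = config.phase_of(hour)
    level = _ARCHETYPE_LEVELS[arch][phase]
    within = 0.0
    if (metabolite_index // len(_ARCHETYPE_LEVELS)) % _N_PHASES == phase:
        within = 0.5 * _within_position(hour, config) * _ARCHETYPE_DIRECTION[arch]
    return config.baseline_log_area + config.effect_scale * (config.phase_gap * level + within)


def _background_baselines(config: SyntheticConfig) -> np.ndarray:
    """Per-background-feature baseline log-areas, fixed by the config seed.

    Drawn from a separate stream so study, QC and external tables generated from
    the same config share identical feature-level parameters.
    """
    rng = np.random.default_rng([config.seed, 7919])
    return config.baseline_log_area + rng.normal(0.0, 1.0, size=config.n_background)


def _log_means_for_label(label: str, config: SyntheticConfig, bg_base: np.ndarray) -> np.ndarray:
    n_panel = len(_panel_feature_names())
    panel_means = np.array(
        [trajectory_mean(j, label, config) for j in range(n_panel)], dtype=float
    )
    return np.concatenate([panel_means, bg_base])


def generate_study(config: SyntheticConfig) -> PeakTable:
    """Generate the study table: control + one group per time point, n_per_group each.

    Areas are exp(trajectory mean + N(0, within_sd)) per feature; background
    features share one label-independent log-normal law.  Bit-reproducible for
    a fixed config.
    """
    rng = np.random.default_rng([config.seed, 1])
    bg_base = _background_baselines(config)
    names = feature_names(config)
    rows, ids, labels = [], [], []
    for label in config.labels:
        mu = _log_means_for_label(label, config, bg_base)
        for rep in range(1, config.n_per_group + 1):
            noise = rng.normal(0.0, config.within_sd, size=len(names))
            rows.append(np.exp(mu + noise))
            ids.append(f"S_{label}_{rep:02d}")
            labels.append(label)
    areas = pd.DataFrame(rows, index=ids, columns=names)
    meta = pd.DataFrame({"label": labels, "role": "study"}, index=ids)
    return PeakTable(areas, meta)


def add_qc(table: PeakTable, config: SyntheticConfig) -> PeakTable:
    """Append pooled-QC rows: expected value = mean of all study rows, noise SD = within_sd/4.

    Emulates pooled quality-control injections (equal-volume mixture of every
    study extract), whose dispersion reflects only instrument variability.
    """
    if config.qc_count < 0:
        raise ValueError("qc_count must be ≥ 0")
    study = table.subset_role("study")
    if study.n_samples < 1:
        raise ValueError("table has no study rows to pool")
    if config.qc_count == 0:
        return table
    rng = np.random.default_rng([config.seed, 2])
    sd = config.within_sd / 4.0
    grand_mean = study.areas.mean(axis=0).to_numpy()
    rows, ids = [], []
    for rep in range(1, config.qc_count + 1):
        noise = rng.normal(0.0, sd, size=grand_mean.size)
        # divide by exp(sd²/2) so the log-normal row has expectation = grand mean
        rows.append(grand_mean * np.exp(noise) / np.exp(0.5 * sd**2))
        ids.append(f"QC_{rep:02d}")
    qc_areas = pd.DataFrame(rows, index=ids, columns=table.feature_ids)
    qc_meta = pd.DataFrame({"label": "unknown", "role": "qc"}, index=ids)
    return table.concat(PeakTable(qc_areas, qc_meta))


def generate_external(
    config: SyntheticConfig, n: int, sd_multiplier: float = 1.0
) -> tuple[PeakTable, dict[str, str]]:
    """Generate ``n`` held-out samples with hidden labels plus the answer key.

    Labels are drawn uniformly over the configured time points (the emulated
    test animals' time distribution is unknown, so uniform is assumed).  The
    returned table carries label ``unknown`` and role ``external``; true labels
    live only in the answer key.  ``sd_multiplier`` optionally inflates the
    within-sample noise to make the external set harder than the study set.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng([config.seed, 3])
    bg_base = _background_baselines(config)
    names = feature_names(config)
    hours = rng.choice(np.asarray(config.timepoints), size=n, replace=True)
    sd = config.within_sd * sd_multiplier
    rows, ids, key = [], [], {}
    for i, hour in enumerate(hours, start=1):
        label = str(int(hour))
        mu = _log_means_for_label(label, config, bg_base)
        rows.append(np.exp(mu + rng.normal(0.0, sd, size=len(names))))
        sample_id = f"EXT_{i:02d}"
        ids.append(sample_id)
        key[sample_id] = label
    areas = pd.DataFrame(rows, index=ids, columns=names)
    meta = pd.DataFrame({"label": "unknown", "role": "external"}, index=ids)
    return PeakTable(areas, meta), key


def null_config(config: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """Convenience: a copy of ``config`` with effect_scale = 0 (no group signal)."""
    base = config if config is not None else SyntheticConfig()
    return replace(base, effect_scale=0.0, **overrides)
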