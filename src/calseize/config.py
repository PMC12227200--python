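"""Pipeline configuration.

One frozen-by-convention dataclass holds every tunable of the analysis:
the moving-window percentile baseline, the event-detection tiers, the
seizure thresholds, the hypoactivity exclusion filter and the alignment
window.  A YAML file with the same field names round-trips through
:func:`PipelineConfig.from_yaml` / :meth:`PipelineConfig.to_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class PipelineConfig:
    """Parameters of the whole-brain activity / seizure analysis.

    Parameters
    ----------
    baseline_window_s
        Width of the moving window for the percentile baseline, in seconds.
        150 s is used for normal brain activity, 300 s for seizure-model
        recordings whose long ictal plateaus would otherwise drag F0 up.
    baseline_percentile
        Percentile of raw fluorescence taken as F0 within each window
        (default 1, i.e. the 1st percentile).
    event_thresholds_pct
        Ascending dF/F0 thresholds (percent) defining the event tiers;
        default ``(5, 10)`` for small and large Ca2+ events.
    seizure_peak_threshold_pct
        Minimum peak dF/F0 (percent) for an excursion to count as a
        seizure (default 100, inclusive).
    seizure_boundary_threshold_pct
        dF/F0 level (percent) whose crossings delimit seizure onset and
        offset (default 50).
    exclusion_amp_pct, exclusion_dur_s
        Seizure-exclusion filter used for interictal hypoactivity
        analysis: events with amplitude above ``exclusion_amp_pct`` AND
        duration above ``exclusion_dur_s`` are dropped.
    exclusion_mode
        ``"and"`` (default, the literal rule) or ``"or"``.
    auc_window_s
        Length of each AUC window in windowed mode (default 300 s = 5 min).
    align_fraction
        Fraction of a seizure's maximum at which traces are aligned
        (default 0.5).
    align_pre_s, align_post_s
        Extent of the aligned segment before/after the alignment point.
    tier_mode
        ``"cumulative"`` ("above x%" by peak amplitude, default),
        ``"band"`` (amplitude in ``[tier, next_tier)``), or ``"rerun"``
        (boundaries re-detected at each tier's own threshold).
    baseline_mode
        ``"centered"`` (default) or ``"trailing"`` moving window.
    roi
        Which column of a multi-ROI table is the whole-brain trace:
        an ROI name, a 0-based index, or ``"mean"`` to average columns.
    """

    baseline_window_s: float = 150.0
    baseline_percentile: float = 1.0
    event_thresholds_pct: Sequence[float] = (5.0, 10.0)
    seizure_peak_threshold_pct: float = 100.0
    seizure_boundary_threshold_pct: float = 50.0
    exclusion_amp_pct: float = 50.0
    exclusion_dur_s: float = 20.0
    exclusion_mode: str = "and"
    auc_window_s: float = 300.0
    align_fraction: float = 0.5
    align_pre_s: float = 0.0
    align_post_s: float = 400.0
    tier_mode: str = "cumulative"
    baseline_mode: str = "centered"
    roi: str | int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_window_s <= 0:
            raise ConfigError("baseline_window_s must be positive")
        if not 0 < self.baseline_percentile <= 100:
            raise ConfigError("baseline_percentile must lie in (0, 100]")
        thr = tuple(float(t) for t in self.event_thresholds_pct)
        if any(t <= 0 for t in thr) or list(thr) != sorted(set(thr)):
            raise ConfigError(
                "event_thresholds_pct must be strictly positive and "
                "strictly ascending"
            )
        self.event_thresholds_pct = thr
        if not self.seizure_boundary_threshold_pct < self.seizure_peak_threshold_pct:
            raise ConfigError("seizure boundary threshold must be below peak threshold")
        if not 0 < self.align_fraction <= 1:
            raise ConfigError("align_fraction must lie in (0, 1]")
        if self.exclusion_mode not in ("and", "or"):
            raise ConfigError("exclusion_mode must be 'and' or 'or'")
        if self.tier_mode not in ("cumulative", "band", "rerun"):
            raise ConfigError("tier_mode must be 'cumulative', 'band' or 'rerun'")
        if self.baseline_mode not in ("centered", "trailing"):
            raise ConfigError("baseline_mode must be 'centered' or 'trailing'")
        if self.align_pre_s < 0 or self.align_post_s < 0:
            raise ConfigError("align_pre_s and align_post_s must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_thresholds_pct"] = list(self.event_thresholds_pct)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)
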