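"""Ca2+ event detection, tier classification, exclusion filter and AUC.

An event is a maximal run of consecutive frames with dF/F0 strictly
above a threshold.  Events are classified into cumulative tiers
("above 5%", "above 10%") by re-running detection per tier, mirroring
how whole-brain activity is scored; a band mode ([5, 10)%) is available
for sensitivity analyses.  The seizure-exclusion filter drops events
that are both large (>50%) and long (>20 s) so that interictal
hypoactivity can be quantified without ictal contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import DffTrace


@dataclass
class CaEvent:
    """One supra-threshold Ca2+ excursion (half-open [onset, offset))."""

    larva_id: str
    onset_s: float
    offset_s: float
    peak_time_s: float
    amplitude_pct: float
    duration_s: float
    detect_threshold_pct: float
    truncated: bool = False


@dataclass
class TierSummary:
    event_count: int
    mean_amplitude_pct: float  # NaN when no events
    mean_duration_s: float     # NaN when no events


@dataclass
class LarvaSummary:
    """Per-larva activity summary: tiered event stats plus AUC."""

    larva_id: str
    group: str
    tiers: Mapping[float, TierSummary]
    auc: float
    auc_normalized: float


def detect_events(trace: DffTrace, threshold_pct: float) -> list[CaEvent]:
    """Maximal runs of frames with dff strictly above ``threshold_pct``.

    Onset is the time of the first supra-threshold frame; offset one
    sampling interval after the last.  Events touching either recording
    edge are kept and flagged ``truncated``.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be positive")
    dff = trace.dff_pct
    t = trace.times_s
    dt = 1.0 / trace.sampling_rate_hz
    mask = dff > threshold_pct
    if not mask.any():
        return []
    starts = np.flatnonzero(mask & ~np.concatenate(([False], mask[:-1])))
    ends = np.flatnonzero(mask & ~np.concatenate((mask[1:], [False])))  # inclusive
    out = []
    for i0, i1 in zip(starts, ends):
        seg = dff[i0 : i1 + 1]
        ipk = i0 + int(np.argmax(seg))
        out.append(
            CaEvent(
                larva_id=trace.larva_id,
                onset_s=float(t[i0]),
                offset_s=float(t[i1] + dt),
                peak_time_s=float(t[ipk]),
                amplitude_pct=float(seg.max()),
                duration_s=float(t[i1] + dt - t[i0]),
                detect_threshold_pct=float(threshold_pct),
                truncated=bool(i0 == 0 or i1 == dff.size - 1),
            )
        )
    return out


def classify_tiers(
    trace: DffTrace,
    tiers: Sequence[float] = (5.0, 10.0),
    mode: str = "cumulative",
) -> dict[float, list[CaEvent]]:
    """Events per threshold tier ("above 5%", "above 10%").

    ``cumulative`` (default) detects events once at the lowest tier and
    assigns an event to every tier its peak amplitude exceeds, so tier
    counts are nested by construction (count above 10% never exceeds
    count above 5%).  ``band`` instead keeps an event only in the
    highest tier below its amplitude ([x, next)%).  ``rerun`` re-runs
    boundary detection at each tier's own threshold; note that one
    low-tier event can then split into several high-tier events, so
    counts are not guaranteed nested in this mode.
    """
    tiers = [float(t) for t in tiers]
    if tiers != sorted(tiers) or len(set(tiers)) != len(tiers):
        raise ValueError("tiers must be strictly ascending")
    if mode not in ("cumulative", "band", "rerun"):
        raise ValueError("mode must be 'cumulative', 'band' or 'rerun'")
    per_tier: dict[float, list[CaEvent]] = {}
    if mode == "rerun":
        for thr in tiers:
            per_tier[thr] = detect_events(trace, thr)
        return per_tier
    base = detect_events(trace, tiers[0])
    for i, thr in enumerate(tiers):
        events = [e for e in base if i == 0 or e.amplitude_pct > thr]
        if mode == "band" and i + 1 < len(tiers):
            nxt = tiers[i + 1]
            events = [e for e in events if e.amplitude_pct < nxt]
        per_tier[thr] = events
    return per_tier


def exclude_seizure_like(
    events: Sequence[CaEvent],
    amp_pct: float = 50.0,
    dur_s: float = 20.0,
    mode: str = "and",
) -> list[CaEvent]:
    """Drop seizure-like events from an event list.

    The default (literal) rule removes events with amplitude > ``amp_pct``
    AND duration > ``dur_s``; ``mode="or"`` removes events exceeding
    either bound.
    """
    if amp_pct <= 0 or dur_s <= 0:
        raise ValueError("amp_pct and dur_s must be positive")
    if mode == "and":
        return [e for e in events if not (e.amplitude_pct > amp_pct and e.duration_s > dur_s)]
    if mode == "or":
        return [e for e in events if not (e.amplitude_pct > amp_pct or e.duration_s > dur_s)]
    raise ValueError("mode must be 'and' or 'or'")


def compute_auc(
    trace: DffTrace,
    mode: str = "whole_trace",
    windows: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Trapezoidal integral of dF/F0 over time, in percent-seconds.

    ``whole_trace`` integrates the full recording; ``windows`` integrates
    each half-open [start, end) window (frames whose timestamps fall
    inside it) and returns the mean of the per-window integrals.
    """
    t = trace.times_s
    dff = trace.dff_pct
    if mode == "whole_trace":
        return float(np.trapezoid(dff, t))
    if mode != "windows":
        raise ValueError("mode must be 'whole_trace' or 'windows'")
    if not windows:
        raise ValueError("windows mode requires a non-empty window list")
    end = trace.t0_s + trace.n_frames / trace.sampling_rate_hz
    vals = []
    for a, b in windows:
        if a >= b:
            raise ValueError(f"empty window [{a}, {b})")
        if a < trace.t0_s - 1e-9 or b > end + 1e-9:
            raise ValueError(f"window [{a}, {b}) outside recording span")
        m = (t >= a) & (t < b)
        if m.sum() < 2:
            raise ValueError(f"window [{a}, {b}) covers fewer than two frames")
        vals.append(np.trapezoid(dff[m], t[m]))
    return float(np.mean(vals))


def summarize_larva(
    events_by_tier: Mapping[float, Sequence[CaEvent]],
    auc: float,
    control_aucs: Sequence[float],
    larva_id: str,
    group: str,
) -> LarvaSummary:
    """Per-larva tier summaries and AUC normalised to the control mean."""
    if len(control_aucs) == 0:
        raise ValueError("control_aucs must be non-empty")
    cmean = float(np.mean(control_aucs))
    if not math.isfinite(cmean) or cmean == 0:
        raise ValueError("control AUC mean is zero or not finite")
    tiers = {}
    for thr, evs in events_by_tier.items():
        if evs:
            tiers[thr] = TierSummary(
                event_count=len(evs),
                mean_amplitude_pct=float(np.mean([e.amplitude_pct for e in evs])),
                mean_duration_s=float(np.mean([e.duration_s for e in evs])),
            )
        else:
            tiers[thr] = TierSummary(0, float("nan"), float("nan"))
    return LarvaSummary(
        larva_id=larva_id, group=group, tiers=tiers,
        auc=float(auc), auc_normalized=float(auc) / cmean,
    )
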