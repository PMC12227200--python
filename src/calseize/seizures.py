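"""Seizure detection, 50%-of-maximum alignment, and seizure metrics.

A seizure is a dF/F0 excursion whose peak reaches at least 100% and
whose extent runs from the first frame above the 50% boundary to the
first frame back below it.  For population overlays, every seizure is
aligned at the first frame reaching 50% of its own maximum, segments
are averaged per time point, and AUC / time-to-peak are measured from
the start of the aligned segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import DffTrace


@dataclass
class Seizure:
    """One detected seizure (half-open [onset, offset) at the boundary)."""

    larva_id: str
    onset_s: float
    offset_s: float
    duration_s: float
    amplitude_pct: float
    peak_time_s: float
    align_time_s: float
    truncated: bool = False
    # frame indices into the source trace, for alignment
    onset_idx: int = 0
    offset_idx: int = 0  # exclusive
    align_idx: int = 0


@dataclass
class AlignedSeizureSet:
    """Seizure segments on a common grid around the alignment point.

    ``traces`` is (n_seizures, n_timepoints) with NaN outside the source
    recording; ``time_axis_s`` is relative to the alignment point (0 at
    the align_fraction crossing).  SEM uses the n-1 normalisation and is
    0 where a single trace contributes.
    """

    time_axis_s: np.ndarray
    traces: np.ndarray
    mean_trace: np.ndarray
    sem_trace: np.ndarray
    larva_ids: tuple[str, ...]
    pre_s: float
    post_s: float
    align_fraction: float


@dataclass
class SeizureMetrics:
    larva_id: str
    auc: float            # %*s over the aligned segment, NaN gaps as 0
    time_to_peak_s: float  # from segment start to maximum


def detect_seizures(
    trace: DffTrace,
    boundary_pct: float = 50.0,
    peak_pct: float = 100.0,
    align_fraction: float = 0.5,
) -> list[Seizure]:
    """Detect seizures as boundary-bounded runs whose peak reaches ``peak_pct``.

    Candidate runs are maximal stretches of frames with dff strictly
    above ``boundary_pct``; a candidate becomes a seizure when its
    maximum is at least ``peak_pct`` (inclusive).  A run still above the
    boundary at the end of the recording is kept and flagged truncated,
    with offset at the trace end.
    """
    if not boundary_pct < peak_pct:
        raise ValueError("boundary_pct must be below peak_pct")
    dff = trace.dff_pct
    t = trace.times_s
    dt = 1.0 / trace.sampling_rate_hz
    mask = dff > boundary_pct
    if not mask.any():
        return []
    starts = np.flatnonzero(mask & ~np.concatenate(([False], mask[:-1])))
    ends = np.flatnonzero(mask & ~np.concatenate((mask[1:], [False])))  # inclusive
    out = []
    for i0, i1 in zip(starts, ends):
        seg = dff[i0 : i1 + 1]
        amp = float(seg.max())
        if amp < peak_pct:
            continue
        truncated = bool(i1 == dff.size - 1)
        offset = float(t[i1] + dt)
        ipk = i0 + int(np.argmax(seg))
        ialign = i0 + int(np.argmax(seg >= align_fraction * amp))
        out.append(
            Seizure(
                larva_id=trace.larva_id,
                onset_s=float(t[i0]),
                offset_s=offset,
                duration_s=offset - float(t[i0]),
                amplitude_pct=amp,
                peak_time_s=float(t[ipk]),
                align_time_s=float(t[ialign]),
                truncated=truncated,
                onset_idx=int(i0),
                offset_idx=int(i1 + 1),
                align_idx=int(ialign),
            )
        )
    return out


def _extract_segment(trace: DffTrace, center_idx: int, n_pre: int, n_post: int) -> np.ndarray:
    seg = np.full(n_pre + n_post, np.nan)
    lo = center_idx - n_pre
    hi = center_idx + n_post
    src_lo, src_hi = max(lo, 0), min(hi, trace.n_frames)
    seg[src_lo - lo : src_hi - lo] = trace.dff_pct[src_lo:src_hi]
    return seg


def align_seizures(
    items: Sequence[tuple[Seizure, DffTrace]] | Sequence[Seizure],
    trace: DffTrace | None = None,
    align_fraction: float = 0.5,
    pre_s: float = 0.0,
    post_s: float = 400.0,
) -> AlignedSeizureSet:
    """Align seizure segments at the ``align_fraction``-of-maximum crossing.

    Accepts either ``(seizure, trace)`` pairs from a cohort or a list of
    seizures plus the single ``trace`` they came from.  Each segment
    covers [align - pre_s, align + post_s), NaN-padded where it leaves
    the recording; the per-timepoint mean and SEM ignore NaNs.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    if trace is not None:
        pairs = [(s, trace) for s in items]  # type: ignore[list-item]
    else:
        pairs = list(items)  # type: ignore[assignment]
    if not pairs:
        raise ValueError("no seizures to align")
    fs = pairs[0][1].sampling_rate_hz
    for _, tr in pairs:
        if tr.sampling_rate_hz != fs:
            raise ValueError("all traces must share one sampling rate")
    n_pre = int(round(pre_s * fs))
    n_post = max(int(round(post_s * fs)), 1)
    rows = []
    ids = []
    for sz, tr in pairs:
        # re-derive the alignment frame at the requested fraction
        run = tr.dff_pct[sz.onset_idx : sz.offset_idx]
        ialign = sz.onset_idx + int(np.argmax(run >= align_fraction * sz.amplitude_pct))
        rows.append(_extract_segment(tr, ialign, n_pre, n_post))
        ids.append(sz.larva_id)
    mat = np.vstack(rows)
    filled = np.nan_to_num(mat, nan=0.0)
    count = np.sum(~np.isnan(mat), axis=0)
    n_safe = np.maximum(count, 1)
    mean = np.where(count > 0, filled.sum(axis=0) / n_safe, np.nan)
    ss = ((np.where(np.isnan(mat), 0.0, mat - mean)) ** 2).sum(axis=0)
    sd = np.where(count > 1, np.sqrt(ss / np.maximum(count - 1, 1)), 0.0)
    sem = np.where(count > 0, sd / np.sqrt(n_safe), np.nan)
    time_axis = (np.arange(-n_pre, n_post)) / fs
    return AlignedSeizureSet(
        time_axis_s=time_axis, traces=mat, mean_trace=mean, sem_trace=sem,
        larva_ids=tuple(ids), pre_s=pre_s, post_s=post_s,
        align_fraction=align_fraction,
    )


def seizure_metrics(aligned: AlignedSeizureSet) -> list[SeizureMetrics]:
    """Per-seizure AUC and time-to-peak over the aligned segment.

    AUC is the trapezoidal integral of the segment with NaN gaps
    contributing 0; time-to-peak runs from the segment start to the
    maximum.  An all-NaN segment is an error.
    """
    fs = 1.0 / (aligned.time_axis_s[1] - aligned.time_axis_s[0])
    out = []
    t = aligned.time_axis_s
    for lid, row in zip(aligned.larva_ids, aligned.traces):
        if np.all(np.isnan(row)):
            raise ValueError("aligned segment holds no data")
        filled = np.nan_to_num(row, nan=0.0)
        auc = float(np.trapezoid(filled, t))
        ipk = int(np.nanargmax(row))
        out.append(SeizureMetrics(larva_id=lid, auc=auc,
                                  time_to_peak_s=float(t[ipk] - t[0])))
    return out


def normalize_to_control(values: Sequence[float], control_values: Sequence[float]) -> np.ndarray:
    """Divide values by the control mean (e.g. seizure AUCs vs control)."""
    c = float(np.mean(control_values))
    if not np.isfinite(c) or c == 0:
        raise ValueError("control mean is zero or not finite")
    return np.asarray(values, dtype=float) / c


def seizing_fraction(n_seizing: int, n_total: int, decimals: int = 2) -> float:
    """Percent of larvae with at least one seizure, rounded for reporting.

    ``decimals`` controls the reported precision (2 for values like
    57.14, 1 for values like 15.8).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_seizing <= n_total:
        raise ValueError("n_seizing must lie in [0, n_total]")
    return round(100.0 * n_seizing / n_total, decimals)
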