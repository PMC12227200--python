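"""Moving-window percentile baseline and dF/F0.

The baseline F0 at frame k is a low percentile (default the 1st) of the
raw fluorescence within a moving window centred on k and truncated at
the recording edges; dF/F0 is then 100*(F - F0)/F0, in percent.  The
low percentile tracks slow drift and photobleaching while ignoring
sparse positive transients, so transient amplitudes survive in dF/F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import PipelineConfig
from .io import Recording


@dataclass
class DffTrace:
    """Baseline and fractional fluorescence change of one recording."""

    larva_id: str
    sampling_rate_hz: float
    baseline: np.ndarray
    dff_pct: np.ndarray
    window_s: float
    group: str = "control"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.dff_pct = np.asarray(self.dff_pct, dtype=float)
        if self.baseline.shape != self.dff_pct.shape or self.baseline.ndim != 1:
            raise ValueError("baseline and dff_pct must be equal-length 1-D arrays")
        if np.any(self.baseline <= 0):
            raise ValueError("baseline must be strictly positive")
        if not np.all(np.isfinite(self.dff_pct)):
            raise ValueError("dff_pct must be finite")

    @property
    def n_frames(self) -> int:
        return self.dff_pct.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.sampling_rate_hz


def estimate_baseline(
    rec: Recording,
    window_s: float = 150.0,
    percentile: float = 1.0,
    mode: str = "centered",
    roi: str | int = 0,
) -> np.ndarray:
    """Per-frame percentile baseline of the whole-brain signal.

    For each frame the window of width ``window_s`` (centred on the frame,
    or trailing when ``mode="trailing"``) is intersected with the
    recording, and the linearly interpolated ``percentile`` of the raw
    values inside it is taken.  A window longer than the recording falls
    back to a single global percentile with a warning.

    Raises
    ------
    ValueError
        If the percentile is out of range, the window shorter than two
        sampling intervals, or the resulting baseline is not strictly
        positive (dF/F0 would be undefined).
    """
    f = rec.trace(roi)
    fs = rec.sampling_rate_hz
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if window_s < 2.0 / fs:
        raise ValueError("window_s must span at least two sampling intervals")
    if mode not in ("centered", "trailing"):
        raise ValueError("mode must be 'centered' or 'trailing'")
    n = f.size
    w = int(round(window_s * fs))
    w = max(w, 2)
    if w >= n:
        warnings.warn(
            "baseline window longer than recording; using a single global percentile",
            stacklevel=2,
        )
        baseline = np.full(n, np.percentile(f, percentile))
    else:
        # offset of the window start relative to the frame index
        back = w // 2 if mode == "centered" else w - 1
        baseline = np.empty(n)
        # frames whose window lies fully inside the recording: vectorised
        lo_full = back                # first such frame
        hi_full = n - (w - back)      # last such frame (inclusive)
        if hi_full >= lo_full:
            sw = sliding_window_view(f, w)
            baseline[lo_full : hi_full + 1] = np.percentile(
                sw[: hi_full - lo_full + 1], percentile, axis=1
            )
        for k in range(min(lo_full, n)):
            baseline[k] = np.percentile(f[max(0, k - back) : min(n, k - back + w)], percentile)
        for k in range(max(hi_full + 1, 0), n):
            baseline[k] = np.percentile(f[max(0, k - back) : min(n, k - back + w)], percentile)
    if np.any(baseline <= 0):
        raise ValueError(
            "baseline is not strictly positive (non-positive fluorescence "
            "throughout a window); dF/F0 is undefined"
        )
    return baseline


def compute_dff(rec: Recording, baseline: np.ndarray, roi: str | int = 0,
                window_s: float = float("nan")) -> DffTrace:
    """dF/F0 in percent: ``100 * (F - F0) / F0`` frame by frame."""
    f = rec.trace(roi)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != f.shape:
        raise ValueError("baseline length must match recording length")
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    dff = 100.0 * (f - baseline) / baseline
    return DffTrace(
        larva_id=rec.larva_id,
        sampling_rate_hz=rec.sampling_rate_hz,
        baseline=baseline,
        dff_pct=dff,
        window_s=window_s,
        group=rec.group,
        t0_s=rec.t0_s,
    )


def dff_trace(rec: Recording, cfg: PipelineConfig | None = None) -> DffTrace:
    """Convenience: baseline estimation + dF/F0 under one config."""
    cfg = cfg or PipelineConfig()
    baseline = estimate_baseline(
        rec, cfg.baseline_window_s, cfg.baseline_percentile,
        mode=cfg.baseline_mode, roi=cfg.roi,
    )
    return compute_dff(rec, baseline, roi=cfg.roi, window_s=cfg.baseline_window_s)
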