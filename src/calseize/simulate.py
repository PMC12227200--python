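"""Synthetic whole-brain recordings, cohorts and qPCR panels.

The generator emulates 1-hour single-ROI wide-field GCaMP traces at
1.33 Hz: a positive baseline with slow multiplicative drift, sparse
Ca2+ transients (linear rise, exponential decay) in a small (5-10%
dF/F0) and a large (10-50%) class, optional seizure waveforms exceeding
100% dF/F0 with gradual onset and either abrupt or slowly tapering
decline, and additive Gaussian noise.  Every emitted recording comes
with its ground truth (kernel parameters and analytic threshold
crossings), so detection can be validated exactly on noiseless traces.

Transients compose multiplicatively with the drifting baseline,
``F = B(t) * (1 + S(t)/100) + noise``, so a kernel of configured
amplitude A contributes exactly A percent dF/F0 wherever the baseline
estimator tracks B(t).  Kernels are placed with a minimum gap so their
analytic crossings stay valid, and event kernels avoid seizure supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Recording
from .qpcr import QpcrPanel, DEFAULT_REFERENCES

#: kernel tail is considered extinguished below this dF/F0 (percent)
TAIL_FLOOR_PCT = 0.5


@dataclass
class DriftParams:
    amplitude_fraction: float = 0.05  # peak fractional baseline excursion
    period_s: float = 1800.0


@dataclass
class EventParams:
    """Transient class: Poisson rate, amplitude range, kernel shape."""

    rate_per_min: float = 1.0
    amplitude_pct_range: tuple[float, float] = (5.0, 10.0)
    rise_s: float = 1.5
    decay_s: float = 4.0


@dataclass
class SeizureParams:
    """Seizure waveforms: linear rise, plateau, abrupt or tapering decline."""

    rate_per_recording: float = 0.0
    count: int | None = None  # exact number, overrides the Poisson draw
    amplitude_pct_range: tuple[float, float] = (120.0, 200.0)
    rise_s: float = 25.0
    plateau_s: float = 10.0
    decay_s: float = 20.0
    decay_shape: str = "abrupt"  # 'abrupt' (linear fall) | 'tapering' (exponential)


@dataclass
class GroupEffect:
    """Multipliers a group applies to the control simulation parameters."""

    small_rate: float = 1.0
    small_amp: float = 1.0
    large_rate: float = 1.0
    large_amp: float = 1.0
    seizure_rate: float = 1.0
    seizure_amp: float = 1.0
    seizure_decay_shape: str | None = None


@dataclass
class SimulationConfig:
    """Study-condition defaults: 1 h at 1.33 Hz, small/large transients."""

    rng_seed: int = 0
    duration_s: float = 3600.0
    sampling_rate_hz: float = 1.33
    baseline_level: float = 100.0
    drift: DriftParams = field(default_factory=DriftParams)
    noise_sd_pct: float = 1.0
    small_event: EventParams = field(default_factory=EventParams)
    large_event: EventParams = field(
        default_factory=lambda: EventParams(
            rate_per_min=0.3, amplitude_pct_range=(10.0, 50.0), rise_s=1.5, decay_s=6.0
        )
    )
    seizure: SeizureParams = field(default_factory=SeizureParams)
    group_effects: Mapping[str, GroupEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ep in (self.small_event, self.large_event):
            if ep.rate_per_min < 0:
                raise ValueError("event rates must be >= 0")
            lo, hi = ep.amplitude_pct_range
            if not 0 < lo <= hi:
                raise ValueError("amplitude ranges must be ordered and positive")
        if self.seizure.rate_per_recording < 0:
            raise ValueError("seizure rate must be >= 0")
        if self.seizure.decay_shape not in ("abrupt", "tapering"):
            raise ValueError("decay_shape must be 'abrupt' or 'tapering'")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration_s and sampling_rate_hz must be positive")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")


@dataclass
class TrueEvent:
    """One seeded transient kernel and its analytic threshold geometry."""

    t0_s: float
    amplitude_pct: float
    rise_s: float
    decay_s: float
    kind: str  # 'small' | 'large'

    def crossing_interval(self, threshold_pct: float) -> tuple[float, float] | None:
        """Analytic [up, down) crossing times of the lone kernel."""
        a = self.amplitude_pct
        if a <= threshold_pct:
            return None
        up = self.t0_s + self.rise_s * threshold_pct / a
        down = self.t0_s + self.rise_s + self.decay_s * math.log(a / threshold_pct)
        return (up, down)


@dataclass
class TrueSeizure:
    """One seeded seizure waveform with analytic 50%-crossing interval."""

    t0_s: float
    amplitude_pct: float
    rise_s: float
    plateau_s: float
    decay_s: float
    decay_shape: str

    def crossing_interval(self, threshold_pct: float = 50.0) -> tuple[float, float]:
        a = self.amplitude_pct
        up = self.t0_s + self.rise_s * threshold_pct / a
        t_plateau_end = self.t0_s + self.rise_s + self.plateau_s
        if self.decay_shape == "abrupt":
            down = t_plateau_end + self.decay_s * (1.0 - threshold_pct / a)
        else:
            down = t_plateau_end + self.decay_s * math.log(a / threshold_pct)
        return (up, down)

    @property
    def support_end_s(self) -> float:
        t_plateau_end = self.t0_s + self.rise_s + self.plateau_s
        if self.decay_shape == "abrupt":
            return t_plateau_end + self.decay_s
        return t_plateau_end + self.decay_s * math.log(
            self.amplitude_pct / TAIL_FLOOR_PCT
        )


@dataclass
class GroundTruth:
    larva_id: str
    group: str
    events: list[TrueEvent]
    seizures: list[TrueSeizure]

    def to_dict(self) -> dict:
        return {
            "larva_id": self.larva_id,
            "group": self.group,
            "events": [asdict(e) for e in self.events],
            "seizures": [asdict(s) for s in self.seizures],
        }

    def expected_event_intervals(
        self, threshold_pct: float, fs: float
    ) -> list[tuple[float, float]]:
        """Analytic supra-threshold [up, down) intervals a detector sampling
        at ``fs`` must find: every kernel (transient or seizure) exceeding
        the threshold whose crossing interval contains >= 1 sample instant."""
        ivals: list[tuple[float, float]] = []
        for e in self.events:
            iv = e.crossing_interval(threshold_pct)
            if iv is not None:
                ivals.append(iv)
        for s in self.seizures:
            if s.amplitude_pct > threshold_pct:
                ivals.append(s.crossing_interval(threshold_pct))
        out = []
        for up, down in sorted(ivals):
            k = math.floor(up * fs) + 1  # first frame strictly after the up-crossing
            if k / fs < down:
                out.append((up, down))
        return out

    def expected_seizure_intervals(
        self, boundary_pct: float = 50.0, peak_pct: float = 100.0, fs: float = 1.33
    ) -> list[tuple[float, float]]:
        """Analytic 50%-crossing intervals of seeded seizures reaching the
        peak rule, restricted to those a sampler at ``fs`` can see."""
        out = []
        for s in sorted(self.seizures, key=lambda x: x.t0_s):
            if s.amplitude_pct < peak_pct:
                continue
            up, down = s.crossing_interval(boundary_pct)
            k = math.floor(up * fs) + 1
            if k / fs < down:
                out.append((up, down))
        return out


@dataclass
class Cohort:
    """Simulated larvae with ground truth, grouped by label."""

    members: list[tuple[Recording, GroundTruth]]

    def recordings(self, group: str | None = None) -> list[Recording]:
        return [r for r, g in self.members if group is None or g.group == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g in self.members:
            seen.setdefault(g.group, None)
        return list(seen)


def _event_kernel(t: np.ndarray, ev: TrueEvent) -> np.ndarray:
    rel = t - ev.t0_s
    out = np.zeros_like(t)
    rising = (rel >= 0) & (rel < ev.rise_s)
    out[rising] = ev.amplitude_pct * rel[rising] / ev.rise_s
    decaying = rel >= ev.rise_s
    tail = ev.amplitude_pct * np.exp(-(rel[decaying] - ev.rise_s) / ev.decay_s)
    # truncate the tail once it is negligible so quiet frames are exactly
    # at baseline and percentile-baseline oracles are exact
    out[decaying] = np.where(tail >= TAIL_FLOOR_PCT, tail, 0.0)
    return out


def _seizure_kernel(t: np.ndarray, sz: TrueSeizure) -> np.ndarray:
    rel = t - sz.t0_s
    out = np.zeros_like(t)
    rising = (rel >= 0) & (rel < sz.rise_s)
    out[rising] = sz.amplitude_pct * rel[rising] / sz.rise_s
    plat = (rel >= sz.rise_s) & (rel < sz.rise_s + sz.plateau_s)
    out[plat] = sz.amplitude_pct
    fall = rel - sz.rise_s - sz.plateau_s
    if sz.decay_shape == "abrupt":
        m = (fall >= 0) & (fall < sz.decay_s)
        out[m] = sz.amplitude_pct * (1.0 - fall[m] / sz.decay_s)
    else:
        m = fall >= 0
        tail = sz.amplitude_pct * np.exp(-fall[m] / sz.decay_s)
        out[m] = np.where(tail >= TAIL_FLOOR_PCT, tail, 0.0)
    return out


def _effective_params(cfg: SimulationConfig, group: str) -> tuple[EventParams, EventParams, SeizureParams]:
    eff = cfg.group_effects.get(group, GroupEffect())
    small = replace(
        cfg.small_event,
        rate_per_min=cfg.small_event.rate_per_min * eff.small_rate,
        amplitude_pct_range=tuple(a * eff.small_amp for a in cfg.small_event.amplitude_pct_range),
    )
    large = replace(
        cfg.large_event,
        rate_per_min=cfg.large_event.rate_per_min * eff.large_rate,
        amplitude_pct_range=tuple(a * eff.large_amp for a in cfg.large_event.amplitude_pct_range),
    )
    seiz = replace(
        cfg.seizure,
        rate_per_recording=cfg.seizure.rate_per_recording * eff.seizure_rate,
        amplitude_pct_range=tuple(a * eff.seizure_amp for a in cfg.seizure.amplitude_pct_range),
        decay_shape=eff.seizure_decay_shape or cfg.seizure.decay_shape,
    )
    return small, large, seiz


def _place_times(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    min_gap: float,
    blocked: Sequence[tuple[float, float]] = (),
    max_tries: int = 2000,
) -> list[float]:
    """Uniform times in [lo, hi) pairwise at least ``min_gap`` apart and
    outside ``blocked`` intervals; rejection-sampled, deterministic."""
    times: list[float] = []
    tries = 0
    while len(times) < n and tries < max_tries:
        tries += 1
        cand = float(rng.uniform(lo, hi))
        if any(abs(cand - x) < min_gap for x in times):
            continue
        if any(b0 - min_gap <= cand < b1 + min_gap for b0, b1 in blocked):
            continue
        times.append(cand)
    times.sort()
    return times


def simulate_recording(
    cfg: SimulationConfig,
    group: str = "control",
    larva_id: str = "larva0",
    rng: np.random.Generator | None = None,
    treatment: str = "none",
) -> tuple[Recording, GroundTruth]:
    """One synthetic whole-brain recording with its ground truth.

    Event counts per class are Poisson with the configured rates (times
    any group multipliers); seizure count is Poisson in the recording,
    or exactly ``cfg.seizure.count`` when set.  The same seed yields
    bit-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    small, large, seiz = _effective_params(cfg, group)
    n = int(round(cfg.duration_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    dur = cfg.duration_s

    # --- seizures first: their supports block event placement
    if seiz.count is not None:
        n_seiz = int(seiz.count)
    else:
        n_seiz = int(rng.poisson(seiz.rate_per_recording))
    amp_hi = seiz.amplitude_pct_range[1]
    if seiz.decay_shape == "abrupt":
        support = seiz.rise_s + seiz.plateau_s + seiz.decay_s
    else:
        support = seiz.rise_s + seiz.plateau_s + seiz.decay_s * math.log(
            max(amp_hi / TAIL_FLOOR_PCT, 2.0)
        )
    seizures: list[TrueSeizure] = []
    margin = 2.0 / cfg.sampling_rate_hz
    if n_seiz > 0:
        starts = _place_times(
            rng, n_seiz, margin, max(dur - support - margin, margin), support + 4 * margin
        )
        for s0 in starts:
            amp = float(rng.uniform(*seiz.amplitude_pct_range))
            seizures.append(
                TrueSeizure(
                    t0_s=s0, amplitude_pct=amp, rise_s=seiz.rise_s,
                    plateau_s=seiz.plateau_s, decay_s=seiz.decay_s,
                    decay_shape=seiz.decay_shape,
                )
            )
    blocked = [(sz.t0_s, sz.support_end_s) for sz in seizures]

    # --- transients, with gaps long enough that tails die below TAIL_FLOOR_PCT
    events: list[TrueEvent] = []
    for params, kind in ((small, "small"), (large, "large")):
        lam = params.rate_per_min * dur / 60.0
        n_ev = int(rng.poisson(lam)) if lam > 0 else 0
        if n_ev == 0:
            continue
        a_hi = params.amplitude_pct_range[1]
        gap = params.rise_s + params.decay_s * math.log(max(a_hi / TAIL_FLOOR_PCT, 2.0))
        other = [(e.t0_s, e.t0_s + gap) for e in events]
        starts = _place_times(
            rng, n_ev, margin, max(dur - gap - margin, margin), gap + 2 * margin,
            blocked=blocked + other,
        )
        for s0 in starts:
            events.append(
                TrueEvent(
                    t0_s=s0,
                    amplitude_pct=float(rng.uniform(*params.amplitude_pct_range)),
                    rise_s=params.rise_s, decay_s=params.decay_s, kind=kind,
                )
            )
    events.sort(key=lambda e: e.t0_s)

    pct = np.zeros(n)
    for ev in events:
        pct += _event_kernel(t, ev)
    for sz in seizures:
        pct += _seizure_kernel(t, sz)

    drift = cfg.drift.amplitude_fraction * np.sin(2 * np.pi * t / cfg.drift.period_s)
    f = cfg.baseline_level * (1.0 + drift) * (1.0 + pct / 100.0)
    if cfg.noise_sd_pct > 0:
        f = f + rng.normal(0.0, cfg.noise_sd_pct / 100.0 * cfg.baseline_level, n)
        f = np.maximum(f, 0.0)
    rec = Recording(
        larva_id=larva_id, group=group, treatment=treatment,
        sampling_rate_hz=cfg.sampling_rate_hz, fluorescence=f,
        roi_names=("whole_brain",),
    )
    truth = GroundTruth(larva_id=larva_id, group=group, events=events, seizures=seizures)
    return rec, truth


def simulate_cohort(
    cfg: SimulationConfig,
    groups: Mapping[str, int],
    seed: int | None = None,
) -> Cohort:
    """Independent recordings per larva; group multipliers applied.

    Each larva gets its own child generator spawned from the seed, so
    permuting group labels permutes outputs without hidden coupling.
    """
    if any(n < 1 for n in groups.values()):
        raise ValueError("every group needs n >= 1")
    root = np.random.SeedSequence(cfg.rng_seed if seed is None else seed)
    members = []
    idx = 0
    children = root.spawn(sum(groups.values()))
    for group, n in groups.items():
        for j in range(n):
            rng = np.random.default_rng(children[idx])
            rec, truth = simulate_recording(
                cfg, group=group, larva_id=f"{group}_{j:03d}", rng=rng
            )
            members.append((rec, truth))
            idx += 1
    return Cohort(members)


def simulate_qpcr(
    true_fold_change: float,
    ct_noise_sd: float = 0.0,
    n_pools: int = 3,
    seed: int = 0,
    target_gene: str = "gal",
    reference_genes: Sequence[str] = DEFAULT_REFERENCES,
    n_replicates: int = 3,
    base_target_ct: float = 28.0,
    reference_cts: Sequence[float] = (18.0, 24.0, 20.0),
) -> QpcrPanel:
    """Synthetic Ct panel with a known target fold change (case/control).

    Reference Cts are constant across conditions; the case-condition
    target Ct is shifted by -log2(fold).  Gaussian noise of sd
    ``ct_noise_sd`` cycles is added per technical replicate (triplicates
    by default).
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    shift = -math.log2(true_fold_change)
    for cond in ("control", "case"):
        for p in range(n_pools):
            sid = f"{cond}_pool{p}"
            gene_ct = {target_gene: base_target_ct + (shift if cond == "case" else 0.0)}
            for gname, ct in zip(reference_genes, reference_cts):
                gene_ct[gname] = ct
            for gname, ct in gene_ct.items():
                for r in range(n_replicates):
                    noisy = ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append(
                        {"sample_id": sid, "condition": cond, "gene": gname,
                         "replicate": r, "ct": noisy}
                    )
    return QpcrPanel(pd.DataFrame(rows), target_gene=target_gene,
                     reference_genes=reference_genes)


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of a config with noise and drift switched off."""
    return replace(cfg, noise_sd_pct=0.0, drift=DriftParams(amplitude_fraction=0.0))
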