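"""End-to-end orchestration: simulate/load -> dF/F0 -> detect -> stats.

Two entry points mirror the two experimental readouts: whole-brain
activity (tiered event statistics and AUC, compared across groups) and
seizure analysis (detection, 50%-of-maximum alignment, per-seizure
metrics and seizing fractions).  Every run returns a RunManifest whose
config snapshot and seed suffice to reproduce it; reports are
deterministic given inputs, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .events import classify_tiers, compute_auc, exclude_seizure_like, summarize_larva
from .io import Recording, write_events_table, write_seizures_table, write_summaries_table
from .preprocess import DffTrace, dff_trace
from .seizures import (
    align_seizures,
    detect_seizures,
    normalize_to_control,
    seizing_fraction,
    seizure_metrics,
)
from .simulate import Cohort
from .stats import GroupComparison, negbin_count_model, normality_gate, rank_sum_test


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    analysis: str
    config: dict
    rng_seed: int
    version: str = __version__
    inputs: list[str] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict | None = None  # populated only when timing is requested

    def to_dict(self) -> dict:
        d = {
            "analysis": self.analysis,
            "config": self.config,
            "rng_seed": self.rng_seed,
            "version": self.version,
            "inputs": self.inputs,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
            "outputs": self.outputs,
        }
        if self.timings_s is not None:
            d["timings_s"] = self.timings_s
        return d


def _cohort_members(cohort) -> list[Recording]:
    if isinstance(cohort, Cohort):
        return [r for r, _ in cohort.members]
    return list(cohort)


def _preprocess_all(recordings: Sequence[Recording], cfg: PipelineConfig) -> list[DffTrace]:
    return [dff_trace(rec, cfg) for rec in recordings]


def _tier_col(thr: float, what: str) -> str:
    # 5.0 -> 'count_5pct'
    s = f"{thr:g}".replace(".", "_")
    return f"{what}_{s}pct"


def run_activity_analysis(
    cohort,
    cfg: PipelineConfig | None = None,
    control_group: str | None = None,
    apply_exclusion: bool = False,
    auc_windows: Sequence[tuple[float, float]] | None = None,
    include_timing: bool = False,
) -> dict:
    """Whole-brain activity analysis across groups.

    Per larva: dF/F0, tiered event detection (optionally with the
    seizure-exclusion filter for interictal hypoactivity), and AUC over
    the whole trace or averaged over the given windows, normalised to
    the control-group mean.  Group comparisons: negative-binomial GLM on
    event counts per tier, rank-sum tests on mean amplitude, mean
    duration and AUC.

    Returns a dict with ``summaries`` (DataFrame), ``comparisons``
    (list of GroupComparison), ``normality`` and ``manifest``.
    """
    cfg = cfg or PipelineConfig()
    t_start = time.perf_counter()
    recordings = _cohort_members(cohort)
    groups: list[str] = list(dict.fromkeys(r.group for r in recordings))
    if len(groups) < 2:
        raise ValueError("activity analysis needs at least two groups")
    control = control_group or groups[0]
    if control not in groups:
        raise ValueError(f"control group {control!r} not present in cohort")
    warnings_list: list[str] = []

    traces = _preprocess_all(recordings, cfg)
    t_preprocess = time.perf_counter()

    per_larva = []
    for tr in traces:
        tiers = classify_tiers(tr, cfg.event_thresholds_pct, mode=cfg.tier_mode)
        if apply_exclusion:
            tiers = {
                thr: exclude_seizure_like(
                    evs, cfg.exclusion_amp_pct, cfg.exclusion_dur_s, cfg.exclusion_mode
                )
                for thr, evs in tiers.items()
            }
        if auc_windows is not None:
            auc = compute_auc(tr, mode="windows", windows=auc_windows)
        else:
            auc = compute_auc(tr, mode="whole_trace")
        per_larva.append((tr, tiers, auc))
    control_aucs = [auc for tr, _, auc in per_larva if tr.group == control]

    rows = []
    all_events = []
    for tr, tiers, auc in per_larva:
        summ = summarize_larva(tiers, auc, control_aucs, tr.larva_id, tr.group)
        row: dict = {"larva_id": summ.larva_id, "group": summ.group}
        for thr, ts in summ.tiers.items():
            row[_tier_col(thr, "count")] = ts.event_count
            row[_tier_col(thr, "mean_amplitude")] = ts.mean_amplitude_pct
            row[_tier_col(thr, "mean_duration")] = ts.mean_duration_s
        row["auc"] = summ.auc
        row["auc_normalized"] = summ.auc_normalized
        rows.append(row)
        for evs in tiers.values():
            all_events.extend(evs)
    summaries = pd.DataFrame(rows).sort_values("larva_id", kind="mergesort").reset_index(drop=True)
    t_detect = time.perf_counter()

    comparisons: list[GroupComparison] = []
    normality: dict = {}
    for other in groups:
        if other == control:
            continue
        ctrl = summaries[summaries["group"] == control]
        case = summaries[summaries["group"] == other]
        for thr in cfg.event_thresholds_pct:
            ccol = _tier_col(thr, "count")
            counts = pd.concat([ctrl[ccol], case[ccol]]).to_numpy()
            labels = [control] * len(ctrl) + [other] * len(case)
            comparisons.append(
                negbin_count_model(counts, labels, measure_name=f"{ccol}:{other}_vs_{control}")
            )
            for what in ("mean_amplitude", "mean_duration"):
                col = _tier_col(thr, what)
                a = ctrl[col].dropna().to_numpy()
                b = case[col].dropna().to_numpy()
                if a.size == 0 or b.size == 0:
                    warnings_list.append(
                        f"no events for {col} in one group ({other} vs {control}); test skipped"
                    )
                    continue
                comparisons.append(
                    rank_sum_test(a, b, measure_name=f"{col}:{other}_vs_{control}",
                                  group_labels=(control, other))
                )
        comparisons.append(
            rank_sum_test(
                ctrl["auc"].to_numpy(), case["auc"].to_numpy(),
                measure_name=f"auc:{other}_vs_{control}", group_labels=(control, other),
            )
        )
        for col in ("auc",):
            vals = {control: ctrl[col].to_numpy(), other: case[col].to_numpy()}
            if all(len(v) >= 3 for v in vals.values()):
                normality[f"{col}:{other}_vs_{control}"] = normality_gate(vals)
            else:
                warnings_list.append(f"normality gate skipped for {col} (n < 3)")
    for c in comparisons:
        warnings_list.extend(c.warnings)
    t_stats = time.perf_counter()

    manifest = RunManifest(
        analysis="activity",
        config=cfg.to_dict(),
        rng_seed=cfg.rng_seed,
        inputs=[r.larva_id for r in recordings],
        stage_counts={
            "recordings": len(recordings),
            "events": len(all_events),
            "comparisons": len(comparisons),
        },
        warnings=warnings_list,
    )
    if include_timing:
        manifest.timings_s = {
            "preprocess": t_preprocess - t_start,
            "detect": t_detect - t_preprocess,
            "stats": t_stats - t_detect,
        }
    return {
        "summaries": summaries,
        "events": all_events,
        "comparisons": comparisons,
        "normality": normality,
        "manifest": manifest,
    }


def run_seizure_analysis(
    cohort,
    cfg: PipelineConfig | None = None,
    control_group: str | None = None,
    include_timing: bool = False,
) -> dict:
    """Seizure detection, alignment, metrics and group comparison.

    Per larva: dF/F0 and seizure detection (peak >= 100%, 50%
    boundaries).  All seizures of a group are aligned at the
    align-fraction crossing; per-seizure AUC and time-to-peak are
    measured from the aligned segment start.  Seizure counts are
    compared by negative-binomial GLM, continuous metrics by rank-sum
    tests (truncated seizures excluded from duration statistics).
    Seizing fractions (percent of larvae with >= 1 seizure) are
    reported per group.
    """
    cfg = cfg or PipelineConfig()
    t_start = time.perf_counter()
    recordings = _cohort_members(cohort)
    if not recordings:
        raise ValueError("cohort is empty")
    groups: list[str] = list(dict.fromkeys(r.group for r in recordings))
    control = control_group or groups[0]
    warnings_list: list[str] = []

    traces = _preprocess_all(recordings, cfg)
    pairs = []  # (seizure, trace)
    counts_per_larva: dict[str, int] = {}
    for tr in traces:
        szs = detect_seizures(
            tr, cfg.seizure_boundary_threshold_pct, cfg.seizure_peak_threshold_pct,
            align_fraction=cfg.align_fraction,
        )
        counts_per_larva[tr.larva_id] = len(szs)
        for sz in szs:
            if sz.truncated:
                warnings_list.append(f"truncated seizure in {tr.larva_id}")
            pairs.append((sz, tr))
    t_detect = time.perf_counter()

    seizure_rows = []
    aligned_by_group: dict[str, object] = {}
    metrics_by_group: dict[str, list] = {}
    for grp in groups:
        grp_pairs = [(s, t) for s, t in pairs if t.group == grp]
        if not grp_pairs:
            continue
        aligned = align_seizures(
            grp_pairs, align_fraction=cfg.align_fraction,
            pre_s=cfg.align_pre_s, post_s=cfg.align_post_s,
        )
        mets = seizure_metrics(aligned)
        aligned_by_group[grp] = aligned
        metrics_by_group[grp] = mets
        for (sz, tr), m in zip(grp_pairs, mets):
            seizure_rows.append(
                {
                    "larva_id": sz.larva_id, "group": grp,
                    "onset_s": sz.onset_s, "offset_s": sz.offset_s,
                    "duration_s": sz.duration_s, "amplitude_pct": sz.amplitude_pct,
                    "peak_time_s": sz.peak_time_s, "align_time_s": sz.align_time_s,
                    "auc": m.auc, "time_to_peak_s": m.time_to_peak_s,
                    "truncated": sz.truncated,
                }
            )
    seizure_table = pd.DataFrame(
        seizure_rows,
        columns=["larva_id", "group", "onset_s", "offset_s", "duration_s",
                 "amplitude_pct", "peak_time_s", "align_time_s", "auc",
                 "time_to_peak_s", "truncated"],
    )
    seizure_table["truncated"] = seizure_table["truncated"].astype(bool)
    if len(seizure_table):
        seizure_table = seizure_table.sort_values(
            ["larva_id", "onset_s"], kind="mergesort"
        ).reset_index(drop=True)

    fractions = {}
    for grp in groups:
        ids = [r.larva_id for r in recordings if r.group == grp]
        n_seizing = sum(1 for lid in ids if counts_per_larva[lid] > 0)
        fractions[grp] = {
            "n_seizing": n_seizing,
            "n_total": len(ids),
            "fraction_pct": seizing_fraction(n_seizing, len(ids)),
        }

    comparisons: list[GroupComparison] = []
    if len(groups) >= 2 and control in groups:
        ctrl_tab = seizure_table[seizure_table["group"] == control]
        for other in groups:
            if other == control:
                continue
            ids_c = [r.larva_id for r in recordings if r.group == control]
            ids_o = [r.larva_id for r in recordings if r.group == other]
            counts = [counts_per_larva[i] for i in ids_c] + [counts_per_larva[i] for i in ids_o]
            labels = [control] * len(ids_c) + [other] * len(ids_o)
            comparisons.append(
                negbin_count_model(counts, labels,
                                   measure_name=f"seizure_count:{other}_vs_{control}")
            )
            case_tab = seizure_table[seizure_table["group"] == other]
            for col in ("amplitude_pct", "duration_s", "auc", "time_to_peak_s"):
                ct, ca = ctrl_tab, case_tab
                if col == "duration_s":  # truncated seizures lack a real offset
                    ct, ca = ct[~ct["truncated"]], ca[~ca["truncated"]]
                a, b = ct[col].to_numpy(), ca[col].to_numpy()
                if a.size == 0 or b.size == 0:
                    warnings_list.append(
                        f"no seizures for {col} in one group ({other} vs {control}); test skipped"
                    )
                    continue
                comparisons.append(
                    rank_sum_test(a, b, measure_name=f"seizure_{col}:{other}_vs_{control}",
                                  group_labels=(control, other))
                )
    for c in comparisons:
        warnings_list.extend(c.warnings)

    # control-normalised seizure AUCs, as in the published overlays
    auc_normalized = None
    if control in metrics_by_group:
        ctrl_aucs = [m.auc for m in metrics_by_group[control]]
        if ctrl_aucs and np.mean(ctrl_aucs) != 0:
            auc_normalized = {
                grp: normalize_to_control([m.auc for m in mets], ctrl_aucs).tolist()
                for grp, mets in metrics_by_group.items()
            }
    t_stats = time.perf_counter()

    manifest = RunManifest(
        analysis="seizure",
        config=cfg.to_dict(),
        rng_seed=cfg.rng_seed,
        inputs=[r.larva_id for r in recordings],
        stage_counts={
            "recordings": len(recordings),
            "seizures": len(seizure_rows),
            "comparisons": len(comparisons),
        },
        warnings=warnings_list,
    )
    if include_timing:
        manifest.timings_s = {
            "detect": t_detect - t_start,
            "align_stats": t_stats - t_detect,
        }
    return {
        "seizure_table": seizure_table,
        "aligned": aligned_by_group,
        "metrics": metrics_by_group,
        "auc_normalized": auc_normalized,
        "seizing_fractions": fractions,
        "comparisons": comparisons,
        "manifest": manifest,
    }


def stats_report_json(result: dict) -> str:
    """Deterministic JSON stats report for either analysis result."""
    payload: dict = {
        "comparisons": [c.to_dict() for c in result.get("comparisons", [])],
    }
    if "seizing_fractions" in result:
        payload["seizing_fractions"] = result["seizing_fractions"]
    if result.get("normality"):
        payload["normality"] = result["normality"]
    return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def write_report(result: dict, outdir: str | Path) -> list[Path]:
    """Write the documented CSV/JSON artefacts of a run; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        written.append(p)

    if "summaries" in result:
        write_summaries_table(result["summaries"], outdir / "summaries.csv")
        written.append(outdir / "summaries.csv")
        write_events_table(result["events"], outdir / "events.csv")
        written.append(outdir / "events.csv")
    if "seizure_table" in result:
        result["seizure_table"].to_csv(outdir / "seizures.csv", index=False)
        written.append(outdir / "seizures.csv")
        for grp, aligned in result["aligned"].items():
            df = pd.DataFrame(
                aligned.traces.T, columns=[f"seizure_{i}" for i in range(aligned.traces.shape[0])]
            )
            df.insert(0, "time_s", aligned.time_axis_s)
            df["mean"] = aligned.mean_trace
            df["sem"] = aligned.sem_trace
            p = outdir / f"aligned_{grp}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    _emit("stats.json", stats_report_json(result))
    manifest = result["manifest"]
    manifest.outputs = [p.name for p in written] + ["manifest.json"]
    _emit("manifest.json", json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return written
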