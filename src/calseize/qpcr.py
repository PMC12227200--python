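"""Relative qPCR quantification: primer efficiency and the ddCt method.

Target-gene expression (galanin transcript, *gal*) is normalised to a
panel of reference genes (*actb1*, *tbp*, *rpl13a*): per sample the
replicate-averaged reference Cts are combined, dCt = Ct_target -
Ct_ref, ddCt contrasts case vs control, and fold change = 2^(-ddCt),
assuming near-perfect (doubling) amplification once primer efficiencies
have been verified equal from dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_REFERENCES = ("actb1", "tbp", "rpl13a")


@dataclass
class QpcrPanel:
    """Ct replicates per sample x gene, with target and reference genes.

    ``data`` columns: sample_id, condition ('control'/'case'), gene,
    replicate, ct.  Every sample must carry the target gene and every
    reference gene with at least one finite Ct.
    """

    data: pd.DataFrame
    target_gene: str = "gal"
    reference_genes: Sequence[str] = DEFAULT_REFERENCES

    def __post_init__(self) -> None:
        need = {"sample_id", "condition", "gene", "ct"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"panel table lacks columns {sorted(missing)}")
        self.reference_genes = tuple(self.reference_genes)
        if not np.isfinite(self.data["ct"]).all():
            raise ValueError("all Ct values must be finite")
        genes_needed = (self.target_gene, *self.reference_genes)
        for sid, sub in self.data.groupby("sample_id"):
            have = set(sub["gene"])
            lack = [gn for gn in genes_needed if gn not in have]
            if lack:
                raise ValueError(f"sample {sid!r} lacks genes {lack}")
        for cond in ("control", "case"):
            if not (self.data["condition"] == cond).any():
                raise ValueError(f"panel holds no {cond!r} samples")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "QpcrPanel":
        return cls(pd.read_csv(path), **kwargs)

    def replicate_means(self) -> pd.DataFrame:
        """Technical replicates averaged: one Ct per sample x gene."""
        return (
            self.data.groupby(["sample_id", "condition", "gene"], as_index=False)["ct"]
            .mean()
        )


@dataclass
class RelativeExpression:
    """Fold change of the target between conditions (case vs control)."""

    contrast: tuple[str, str]  # (control, case)
    fold_change: float
    ddct: float
    per_sample_fold: Mapping[str, float]  # sample -> 2^-(dCt - mean control dCt)

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")


def primer_efficiency(
    dilution_log10: Sequence[float], ct_means: Sequence[float]
) -> dict[str, float]:
    """Amplification efficiency from a dilution series.

    Least-squares slope of mean Ct against log10(relative template
    amount); efficiency = 10^(-1/slope) - 1 as a fraction (1.0 = perfect
    doubling, slope -3.3219).  ``acceptable`` flags efficiencies within
    [0.9, 1.1].
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct_means, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired dilution points")
    if np.ptp(x) == 0:
        raise ValueError("dilution series is degenerate (constant)")
    res = sps.linregress(x, y)
    slope = float(res.slope)
    if slope == 0:
        raise ValueError("flat Ct-vs-dilution line; efficiency undefined")
    eff = 10.0 ** (-1.0 / slope) - 1.0
    return {
        "slope": slope,
        "efficiency": float(eff),
        "r_squared": float(res.rvalue**2),
        "acceptable": bool(0.9 <= eff <= 1.1),
    }


def _reference_ct(sub: pd.DataFrame, reference_genes: Sequence[str],
                  ref_aggregation: str) -> float:
    refs = sub[sub["gene"].isin(reference_genes)].set_index("gene")["ct"]
    ref_cts = refs.loc[list(reference_genes)].to_numpy(dtype=float)
    if ref_aggregation == "mean_ct":
        return float(np.mean(ref_cts))
    if ref_aggregation == "geomean_expression":
        # geometric mean of per-reference relative levels 2^-Ct; its
        # -log2 equals the arithmetic mean Ct, so the two modes agree.
        return float(-np.log2(sps.gmean(2.0 ** (-ref_cts))))
    raise ValueError("ref_aggregation must be 'mean_ct' or 'geomean_expression'")


def relative_expression(
    panel: QpcrPanel,
    ref_aggregation: str = "mean_ct",
    efficiencies: Mapping[str, float] | None = None,
) -> RelativeExpression:
    """Fold change of the target gene, case vs control, by ddCt.

    Per sample: dCt = Ct_target - Ct_ref where Ct_ref combines the
    replicate-averaged reference Cts (arithmetic mean by default; the
    geometric-mean-of-expression mode is algebraically identical).
    ddCt = mean dCt(case) - mean dCt(control); fold = 2^(-ddCt).

    When ``efficiencies`` maps genes to measured fractional efficiencies,
    an efficiency-corrected (Pfaffl-style) ratio is computed instead,
    using per-gene amplification bases (1 + E).
    """
    means = panel.replicate_means()
    dcts: dict[str, float] = {}
    conds: dict[str, str] = {}
    ratios: dict[str, float] = {}
    for (sid, cond), sub in means.groupby(["sample_id", "condition"]):
        tgt = sub.loc[sub["gene"] == panel.target_gene, "ct"]
        if tgt.empty:
            raise ValueError(f"sample {sid!r} lacks the target gene")
        tgt_ct = float(tgt.mean())
        conds[str(sid)] = str(cond)
        if efficiencies is None:
            dcts[str(sid)] = tgt_ct - _reference_ct(
                sub, panel.reference_genes, ref_aggregation
            )
        else:
            bt = 1.0 + float(efficiencies[panel.target_gene])
            num = bt ** (-tgt_ct)
            ref_levels = []
            refs = sub[sub["gene"].isin(panel.reference_genes)].set_index("gene")["ct"]
            for gname in panel.reference_genes:
                br = 1.0 + float(efficiencies[gname])
                ref_levels.append(br ** (-float(refs.loc[gname])))
            ratios[str(sid)] = num / float(sps.gmean(ref_levels))
    if efficiencies is None:
        ctrl_d = [d for s, d in dcts.items() if conds[s] == "control"]
        case_d = [d for s, d in dcts.items() if conds[s] == "case"]
        ddct = float(np.mean(case_d) - np.mean(ctrl_d))
        fold = float(2.0 ** (-ddct))
        per_sample = {
            s: float(2.0 ** (-(d - np.mean(ctrl_d)))) for s, d in dcts.items()
        }
    else:
        ctrl_r = [r for s, r in ratios.items() if conds[s] == "control"]
        case_r = [r for s, r in ratios.items() if conds[s] == "case"]
        cmean = float(sps.gmean(ctrl_r))
        fold = float(sps.gmean(case_r)) / cmean
        ddct = float(-np.log2(fold))
        per_sample = {s: r / cmean for s, r in ratios.items()}
    return RelativeExpression(
        contrast=("control", "case"),
        fold_change=fold,
        ddct=ddct,
        per_sample_fold=per_sample,
    )
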