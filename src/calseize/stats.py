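"""Group statistics: normality gate, rank-sum tests, negative-binomial GLM.

Continuous per-larva or per-seizure measures (amplitude, duration, AUC,
time to peak) are compared with the two-sided Wilcoxon–Mann–Whitney
test; event and seizure counts, being overdispersed, are compared with
a negative-binomial (gamma–Poisson) GLM with a log link.  Shapiro–Wilk
normality results are reported for transparency but do not switch the
test: the pipeline stays nonparametric for continuous measures.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

P_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupComparison:
    """Result of one two-group comparison."""

    measure_name: str
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    statistic: float
    p_value: float
    test: str  # rank_sum | negbin_glm | shapiro_gate
    effect: float  # difference of medians (b-a) or rate ratio (b/a)
    significance_label: str = "ns"
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "measure_name": self.measure_name,
            "group_labels": list(self.group_labels),
            "n_per_group": list(self.n_per_group),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test": self.test,
            "effect": self.effect,
            "significance_label": self.significance_label,
            "warnings": list(self.warnings),
        }


def label_significance(p: float) -> str:
    """Map a p-value to the conventional star label (ns above 0.05)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    for thr, lab in P_THRESHOLDS:
        if p < thr:
            return lab
    return "ns"


def normality_gate(groups: Mapping[str, Sequence[float]]) -> dict[str, dict]:
    """Shapiro–Wilk W and p per group (report only; tests stay nonparametric).

    Groups need at least 3 values; a zero-variance sample is flagged
    degenerate instead of tested.
    """
    out: dict[str, dict] = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {label!r} needs n >= 3 for Shapiro-Wilk")
        if np.ptp(v) == 0:
            out[label] = {"W": float("nan"), "p": float("nan"), "degenerate": True}
            continue
        w, p = sps.shapiro(v)
        out[label] = {"W": float(w), "p": float(p), "degenerate": False}
    return out


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    measure_name: str = "",
    group_labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Wilcoxon–Mann–Whitney test.

    The exact null distribution is enumerated when the smaller group has
    at most 8 values and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction (and continuity correction)
    is used.  The effect is the difference of medians, b minus a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        measure_name=measure_name,
        group_labels=group_labels,
        n_per_group=(int(a.size), int(b.size)),
        statistic=float(res.statistic),
        p_value=p,
        test="rank_sum",
        effect=float(np.median(b) - np.median(a)),
        significance_label=label_significance(p),
        warnings=() if exact else ("normal approximation with tie correction",),
    )


def negbin_count_model(
    counts: Sequence[int],
    group: Sequence[str],
    measure_name: str = "event_count",
    p_method: str = "wald",
) -> GroupComparison:
    """Negative-binomial GLM of counts on a two-level group indicator.

    Fits log(mu) = b0 + b1 * [group == reference-complement] by maximum
    likelihood with the NB2 dispersion estimated jointly.  The effect is
    the rate ratio exp(b1) of the second group over the first (groups
    ordered by first appearance).  ``p_method`` selects the Wald p-value
    (default) or a likelihood-ratio test against the intercept-only model.
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    labels = list(dict.fromkeys(group))  # unique, order of first appearance
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g = np.asarray([labels.index(x) for x in group], dtype=float)
    warn_list: list[str] = []
    for lab, gi in zip(labels, (0.0, 1.0)):
        if np.all(y[g == gi] == 0):
            warn_list.append(f"all-zero counts in group {lab!r}; fit unstable")
    X = sm.add_constant(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        fit = None
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception:
            try:
                fit = model.fit(disp=0, maxiter=500, method="nm")
            except Exception:
                pass
        if fit is None:
            # degenerate data (e.g. all zeros, perfect separation): report
            # the empirical rate ratio without a test
            warn_list.append("negative-binomial fit failed; no p-value")
            mean_a, mean_b = float(np.mean(y[g == 0])), float(np.mean(y[g == 1]))
            effect = mean_b / mean_a if mean_a > 0 else float("nan")
            return GroupComparison(
                measure_name=measure_name,
                group_labels=(labels[0], labels[1]),
                n_per_group=(int(np.sum(g == 0)), int(np.sum(g == 1))),
                statistic=float("nan"),
                p_value=1.0,
                test="negbin_glm",
                effect=effect,
                significance_label="ns",
                warnings=tuple(warn_list),
            )
        if not getattr(fit, "mle_retvals", {}).get("converged", True):
            warn_list.append("maximum-likelihood fit did not converge")
        coef = float(fit.params[1])
        if p_method == "wald":
            try:
                p = float(fit.pvalues[1])
                stat = float(fit.tvalues[1])
            except (np.linalg.LinAlgError, ValueError):
                # singular Hessian (e.g. boundary dispersion); no usable Wald test
                warn_list.append("singular covariance; Wald p-value unavailable")
                p, stat = float("nan"), float("nan")
        elif p_method == "lrt":
            null = sm.NegativeBinomial(y, np.ones((y.size, 1))).fit(disp=0, maxiter=200)
            stat = float(2 * (fit.llf - null.llf))
            p = float(sps.chi2.sf(max(stat, 0.0), df=1))
        else:
            raise ValueError("p_method must be 'wald' or 'lrt'")
        if not np.isfinite(p):
            # dispersion collapsed to the zero boundary (data not
            # overdispersed): the NB information matrix is singular, but
            # the model then reduces to Poisson, whose Wald test is valid
            try:
                pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                coef = float(pois.params[1])
                stat = float(pois.tvalues[1])
                p = float(pois.pvalues[1])
                warn_list.append("dispersion at zero boundary; Poisson fallback")
            except Exception:
                pass
    if not np.isfinite(p):
        warn_list.append("non-finite p-value from unstable fit")
        p = 1.0
    p = float(min(max(p, 0.0), 1.0))
    return GroupComparison(
        measure_name=measure_name,
        group_labels=(labels[0], labels[1]),
        n_per_group=(int(np.sum(g == 0)), int(np.sum(g == 1))),
        statistic=stat,
        p_value=p,
        test="negbin_glm",
        effect=float(np.exp(coef)),
        significance_label=label_significance(p),
        warnings=tuple(warn_list),
    )
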