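"""Dual-luciferase reporter scoring and the enhancer decision tree.

Per-well activity is firefly / renilla. A construct's summary activity is
the unweighted mean of its transfection-batch means. The decision tree:

* minP call — candidate / minP-baseline fold >= ``fold_threshold`` (default
  5, inclusive; log2(5) = 2.32).
* own-promoter call — one-way ANOVA of candidate vs promoter-only wells
  (two groups, so F = pooled t^2), positive when p < alpha (default 0.01)
  AND the candidate mean exceeds the baseline mean.
* target-specificity — own-promoter positive in the target line and
  negative in every control line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WellSummary",
    "MinPCall",
    "PromoterCall",
    "normalized_activity",
    "call_minP_enhancer",
    "call_promoter_enhancer",
    "call_erythroid_specific",
    "categorize_site",
    "EnhancerCall",
    "DEFAULT_FOLD_THRESHOLD",
    "DEFAULT_ALPHA",
]

DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class WellSummary:
    """Summary of one construct's wells in one cell line."""

    mean_activity: float  # mean of batch means
    sd: float  # sd across all wells (ddof=1)
    batch_means: tuple[float, ...]
    n_wells: int
    warnings: tuple[str, ...] = ()


def normalized_activity(
    firefly: Sequence[float],
    renilla: Sequence[float],
    batches: Sequence[int],
) -> WellSummary:
    """Per-well firefly/renilla ratios rolled up into a construct summary.

    Raises ``ValueError`` on any non-positive renilla reading. Fewer than
    two batches is legal but recorded as a warning in the summary.
    """
    f = np.asarray(firefly, dtype=float)
    r = np.asarray(renilla, dtype=float)
    b = np.asarray(batches)
    if f.shape != r.shape or f.shape != b.shape:
        raise ValueError("firefly, renilla and batches must align")
    if f.size == 0:
        raise ValueError("no wells")
    if np.any(r <= 0):
        raise ValueError("renilla must be positive in every well")
    ratios = f / r
    batch_ids = sorted(set(b.tolist()))
    batch_means = tuple(float(ratios[b == bid].mean()) for bid in batch_ids)
    warnings = ()
    if len(batch_ids) < 2:
        warnings = ("fewer than 2 transfection batches",)
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return WellSummary(
        mean_activity=float(np.mean(batch_means)),
        sd=sd,
        batch_means=batch_means,
        n_wells=int(f.size),
        warnings=warnings,
    )


@dataclass(frozen=True)
class MinPCall:
    fold: float
    log2_fold: float
    is_enhancer: bool


def call_minP_enhancer(
    candidate_summary: float,
    baseline_summary: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> MinPCall:
    """Fold activation of the minimal-promoter baseline; threshold inclusive."""
    if baseline_summary <= 0:
        raise ValueError("baseline activity must be positive")
    fold = candidate_summary / baseline_summary
    return MinPCall(
        fold=fold,
        log2_fold=math.log2(fold) if fold > 0 else float("-inf"),
        is_enhancer=fold >= fold_threshold,
    )


@dataclass(frozen=True)
class PromoterCall:
    fold_pct: float  # baseline = 100%
    p_value: float
    is_enhancer: bool


def call_promoter_enhancer(
    candidate_wells: Sequence[float],
    baseline_wells: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> PromoterCall:
    """Candidate-vs-baseline one-way ANOVA on normalized well ratios.

    Wells are firefly/renilla ratios; the baseline group is normalized to
    100%. With two groups the ANOVA F statistic equals the squared pooled-t
    statistic. Zero variance in both groups with equal means yields p = 1
    (no call) rather than an exception.
    """
    cand = np.asarray(candidate_wells, dtype=float)
    base = np.asarray(baseline_wells, dtype=float)
    if cand.size < 3 or base.size < 3:
        raise ValueError(">=3 wells per group required")
    base_mean = base.mean()
    if base_mean <= 0:
        raise ValueError("baseline mean activity must be positive")
    cand_pct = cand / base_mean * 100.0
    base_pct = base / base_mean * 100.0
    if np.ptp(cand_pct) == 0 and np.ptp(base_pct) == 0:
        pval = 1.0 if cand_pct[0] == base_pct[0] else 0.0
    else:
        pval = float(stats.f_oneway(cand_pct, base_pct).pvalue)
    fold_pct = float(cand_pct.mean())
    return PromoterCall(
        fold_pct=fold_pct,
        p_value=pval,
        is_enhancer=bool(pval < alpha and fold_pct > 100.0),
    )


def call_erythroid_specific(
    promoter_calls: Mapping[str, bool],
    target_line: str,
    control_lines: Sequence[str],
) -> bool:
    """True iff the own-promoter call is positive in the target line and
    negative in every control line. Missing evaluations are errors."""
    if target_line not in promoter_calls:
        raise KeyError(f"no promoter call for target line {target_line!r}")
    for line in control_lines:
        if line not in promoter_calls:
            raise KeyError(f"no promoter call for control line {line!r}")
    return bool(promoter_calls[target_line]) and not any(
        promoter_calls[line] for line in control_lines
    )


def categorize_site(minP_enhancer: bool, promoter_enhancer_target: bool) -> str:
    """Cross of the two boolean calls in the target line."""
    if minP_enhancer and promoter_enhancer_target:
        return "dual"
    if minP_enhancer:
        return "minP_only"
    if promoter_enhancer_target:
        return "promoter_only"
    return "non_enhancer"


@dataclass(frozen=True)
class EnhancerCall:
    """Full decision-tree output for one site."""

    site_id: str
    minP_fold: float
    minP_enhancer: bool
    promoter_fold_pct: float
    promoter_p_value: float
    promoter_enhancer: Mapping[str, bool]
    erythroid_specific_enhancer: bool
    category: str
    is_positive_control: bool = False
    audit: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        target_calls = dict(self.promoter_enhancer)
        if self.erythroid_specific_enhancer and target_calls:
            # specificity implies a positive target-line promoter call
            if not any(target_calls.values()):
                raise ValueError(
                    f"{self.site_id}: specific enhancer without promoter call"
                )
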