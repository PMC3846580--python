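"""Expression screening: RPKM normalization, up-regulation calls and
qPCR-style relative quantification (2^-ddCt) with per-condition t-tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionCall",
    "QpcrResult",
    "rpkm",
    "call_upregulated",
    "qpcr_relative_expression",
    "DETECTION_FLOOR",
]

#: Genes whose maximum RPKM across samples falls below this are dropped.
DETECTION_FLOOR = 0.01


@dataclass(frozen=True)
class CountMatrix:
    """Read counts per gene and sample with gene lengths and library sizes.

    ``counts`` is genes x samples; ``gene_lengths`` in bp;
    ``total_mapped_reads`` per sample (may exceed the column sum since not
    every mapped read lands in an annotated gene).
    """

    gene_ids: tuple[str, ...]
    gene_lengths: np.ndarray  # bp, > 0
    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    total_mapped_reads: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        n_g, n_s = len(self.gene_ids), len(self.sample_ids)
        if self.counts.shape != (n_g, n_s):
            raise ValueError("counts shape mismatch")
        if len(self.conditions) != n_s:
            raise ValueError("one condition per sample required")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        if np.any(self.total_mapped_reads < colsum):
            raise ValueError("total_mapped_reads below column sum of counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of gene model per million mapped reads.

    ``rpkm[g, s] = counts[g, s] / ((length_g / 1e3) * (library_s / 1e6))``.
    """
    if np.any(counts.total_mapped_reads <= 0):
        raise ValueError("zero library size")
    kb = counts.gene_lengths[:, None] / 1e3
    millions = counts.total_mapped_reads[None, :] / 1e6
    mat = counts.counts / (kb * millions)
    return pd.DataFrame(mat, index=list(counts.gene_ids), columns=list(counts.sample_ids))


@dataclass(frozen=True)
class ExpressionCall:
    """Detection and up-regulation status per gene.

    ``upregulated_in_target`` is a nullable boolean series: ``pd.NA`` marks
    genes below the detection floor (not evaluable, distinct from False).
    """

    rpkm: pd.DataFrame
    detected: pd.Series
    upregulated_in_target: pd.Series


def call_upregulated(
    expr_rpkm: pd.DataFrame,
    target_samples: Sequence[str],
    reference_sample: str,
    detection_floor: float = DETECTION_FLOOR,
    rule: Literal["all", "mean"] = "all",
) -> ExpressionCall:
    """Call genes up-regulated in target samples relative to the reference.

    Under the default ``"all"`` rule a gene is up-regulated iff its RPKM in
    every target sample strictly exceeds the reference sample's; the
    ``"mean"`` alternative compares the mean over target samples instead.
    Genes whose max RPKM across all samples is below ``detection_floor``
    are undetected and not evaluable.
    """
    missing = [s for s in (*target_samples, reference_sample) if s not in expr_rpkm]
    if missing:
        raise KeyError(f"samples not in RPKM matrix: {missing}")
    detected = expr_rpkm.max(axis=1) >= detection_floor
    ref = expr_rpkm[reference_sample]
    tgt = expr_rpkm[list(target_samples)]
    if rule == "all":
        up = tgt.gt(ref, axis=0).all(axis=1)
    elif rule == "mean":
        up = tgt.mean(axis=1) > ref
    else:
        raise ValueError(f"unknown rule {rule!r}")
    up = up.astype("boolean").mask(~detected, pd.NA)
    return ExpressionCall(rpkm=expr_rpkm, detected=detected, upregulated_in_target=up)


@dataclass(frozen=True)
class QpcrResult:
    """Fold changes (2^-ddCt) and t-test p-values per gene and condition.

    ``fold`` has a row per (gene, condition, replicate); ``summary`` one row
    per (gene, condition) with mean fold and the p-value of the condition
    vs calibrator t-test on dCt replicates, plus significance tiers.
    """

    fold: pd.DataFrame
    summary: pd.DataFrame
    reference_gene: str
    calibrator_condition: str


def qpcr_relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
    tiers: tuple[float, float] = (0.005, 0.001),
    welch: bool = False,
) -> QpcrResult:
    """Relative quantification from a long-format Ct table.

    ``ct`` needs columns ``gene``, ``sample``, ``condition``, ``replicate``,
    ``ct``. Per sample replicate, dCt = Ct_gene - Ct_reference; per gene,
    ddCt = dCt - mean dCt over the calibrator condition; fold = 2^-ddCt.
    Two-sided independent-samples t-tests compare each non-calibrator
    condition's dCt replicates against the calibrator's (pooled variance by
    default, Welch when ``welch=True``).
    """
    required = {"gene", "sample", "condition", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "replicate"])["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")

    genes = ct[ct["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(genes[["sample", "replicate"]])
    if not key.isin(ref.index).all():
        raise ValueError("missing reference-gene Ct for some sample/replicate")
    genes["dct"] = genes["ct"].to_numpy() - ref.loc[key].to_numpy()

    rows = []
    summaries = []
    lo_tier, hi_tier = max(tiers), min(tiers)
    for gene, sub in genes.groupby("gene", sort=False):
        calib = sub.loc[sub["condition"] == calibrator_condition, "dct"]
        if calib.empty:
            raise ValueError(f"{gene}: no calibrator-condition replicates")
        baseline = calib.mean()
        ddct = sub["dct"] - baseline
        fold = np.power(2.0, -ddct)
        rows.append(sub.assign(ddct=ddct, fold=fold))
        for cond, csub in sub.groupby("condition", sort=False):
            mean_fold = float(np.power(2.0, -(csub["dct"] - baseline)).mean())
            if cond == calibrator_condition:
                pval = np.nan
            else:
                if len(csub) < 2 or len(calib) < 2:
                    raise ValueError(
                        f"{gene}/{cond}: >=2 replicates per condition required"
                    )
                pval = float(
                    stats.ttest_ind(
                        csub["dct"], calib, equal_var=not welch
                    ).pvalue
                )
            summaries.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_fold": mean_fold,
                    "p_value": pval,
                    "significant": bool(pval < lo_tier) if np.isfinite(pval) else False,
                    "highly_significant": bool(pval < hi_tier)
                    if np.isfinite(pval)
                    else False,
                }
            )

    return QpcrResult(
        fold=pd.concat(rows, ignore_index=True),
        summary=pd.DataFrame(summaries),
        reference_gene=reference_gene,
        calibrator_condition=calibrator_condition,
    )
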