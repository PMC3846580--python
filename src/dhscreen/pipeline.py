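"""End-to-end pipeline: configuration, stage orchestration and run report.

Stages run in the order expression -> specificity -> reporter -> evidence ->
summary. A stage whose inputs are absent is skipped and recorded as such.
The reporter and evidence stages have a *call-replay* mode that consumes a
transcribed boolean call/evidence table instead of raw wells and tracks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import evidence as ev
from . import io as dio
from . import reporter as rep
from .expression import call_upregulated, qpcr_relative_expression, rpkm
from .intervals import annotate_position, define_locus_domain
from .specificity import CellTypePanel, ERYTHROID_PANEL, screen_locus

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "score_plate"]


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run."""

    outdir: Path
    gene_models: Path | None = None
    peaks_dir: Path | None = None
    counts: Path | None = None
    qpcr: Path | None = None
    plate: Path | None = None
    tracks_dir: Path | None = None
    replay_table: Path | None = None

    panel: CellTypePanel = ERYTHROID_PANEL
    upstream: int = 70_000
    downstream: int = 20_000
    subdued_ratio: float = 0.5
    max_nontarget_presence: int = 2
    fold_threshold: float = 5.0
    alpha: float = 0.01
    qpcr_tiers: tuple[float, float] = (0.005, 0.001)
    k: int = 3
    seed: int = 0
    target_line: str = "K562"
    control_lines: tuple[str, ...] = ("HeLa", "HEK293")
    reference_condition: str = "HESC"
    fdr_note: str = "peak presence called upstream at FDR 0.5%"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        panel = raw.pop("panel", None)
        kwargs = {}
        for key in ("outdir", "gene_models", "peaks_dir", "counts", "qpcr",
                    "plate", "tracks_dir", "replay_table"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw.pop(key))
            else:
                raw.pop(key, None)
        for key in ("qpcr_tiers", "control_lines"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        if panel:
            kwargs["panel"] = CellTypePanel(
                target=tuple(panel["target"]), non_target=tuple(panel["non_target"])
            )
        return cls(**kwargs)


@dataclass
class StageRecord:
    name: str
    ran: bool
    params: Mapping[str, object] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()
    outputs: Mapping[str, str] = field(default_factory=dict)  # path -> sha256


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)

    def record(self, name: str, ran: bool, params=None, warnings=(), outputs=()):
        digests = {str(p): _sha256(p) for p in outputs}
        self.stages.append(
            StageRecord(name, ran, dict(params or {}), tuple(warnings), digests)
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "ran": s.ran, "params": {k: str(v) for k, v in s.params.items()},
                 "warnings": list(s.warnings), "outputs": dict(s.outputs)}
                for s in self.stages
            ]
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def score_plate(
    plate: pd.DataFrame,
    fold_threshold: float = 5.0,
    alpha: float = 0.01,
    target_line: str = "K562",
    control_lines: Sequence[str] = ("HeLa", "HEK293"),
) -> list[rep.EnhancerCall]:
    """Run the full decision tree on a well-level plate table.

    Baselines are the ``insert == "none"`` constructs of each promoter and
    cell line; the minP baseline must exist in the target line. Positive
    controls are scored like candidates but flagged and never gate calls.
    """
    def ratios(sub: pd.DataFrame):
        return (sub["firefly"] / sub["renilla"]).to_numpy()

    def summary(sub: pd.DataFrame) -> rep.WellSummary:
        return rep.normalized_activity(
            sub["firefly"].to_numpy(), sub["renilla"].to_numpy(),
            sub["batch"].to_numpy(),
        )

    minp_base = plate[
        (plate["promoter"] == "minP")
        & (plate["insert"] == "none")
        & (plate["cell_line"] == target_line)
    ]
    if minp_base.empty:
        raise ValueError("no minP baseline wells in the target line")
    minp_base_summary = summary(minp_base).mean_activity

    calls = []
    inserts = [i for i in plate["insert"].unique() if i != "none"]
    for insert in sorted(inserts):
        sub = plate[plate["insert"] == insert]
        warnings: list[str] = []

        minp_fold, minp_flag = float("nan"), False
        cand_minp = sub[(sub["promoter"] == "minP") & (sub["cell_line"] == target_line)]
        if not cand_minp.empty:
            s = summary(cand_minp)
            warnings.extend(s.warnings)
            mc = rep.call_minP_enhancer(s.mean_activity, minp_base_summary, fold_threshold)
            minp_fold, minp_flag = mc.fold, mc.is_enhancer

        promoter_calls: dict[str, bool] = {}
        fold_pct, p_value = float("nan"), float("nan")
        own = sub[sub["promoter"] != "minP"]
        for line in (target_line, *control_lines):
            cand = own[own["cell_line"] == line]
            if cand.empty:
                continue
            prom = cand["promoter"].iloc[0]
            base = plate[
                (plate["promoter"] == prom)
                & (plate["insert"] == "none")
                & (plate["cell_line"] == line)
            ]
            if base.empty:
                raise ValueError(f"{insert}: no {prom} baseline wells in {line}")
            pc = rep.call_promoter_enhancer(ratios(cand), ratios(base), alpha)
            promoter_calls[line] = pc.is_enhancer
            if line == target_line:
                fold_pct, p_value = pc.fold_pct, pc.p_value

        if promoter_calls and all(
            line in promoter_calls for line in (target_line, *control_lines)
        ):
            specific = rep.call_erythroid_specific(
                promoter_calls, target_line, control_lines
            )
        else:
            specific = False
            if promoter_calls:
                warnings.append("incomplete cell-line coverage for specificity call")

        calls.append(
            rep.EnhancerCall(
                site_id=insert,
                minP_fold=minp_fold,
                minP_enhancer=minp_flag,
                promoter_fold_pct=fold_pct,
                promoter_p_value=p_value,
                promoter_enhancer=promoter_calls,
                erythroid_specific_enhancer=specific,
                category=rep.categorize_site(
                    minp_flag, promoter_calls.get(target_line, False)
                ),
                is_positive_control=insert == "positive_control",
                audit={"warnings": tuple(warnings)},
            )
        )
    return calls


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages and write their outputs under
    ``config.outdir``. Returns the per-stage run report (also written as
    ``run_report.json``)."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # ---- expression -------------------------------------------------------
    if cfg.counts is not None and Path(cfg.counts).exists():
        counts = dio.read_counts(cfg.counts)
        mat = rpkm(counts)
        cond = dict(zip(counts.sample_ids, counts.conditions))
        targets = [s for s in counts.sample_ids if cond[s] != cfg.reference_condition]
        ref = next(s for s in counts.sample_ids if cond[s] == cfg.reference_condition)
        call = call_upregulated(mat, targets, ref)
        rpkm_path = out / "rpkm.tsv"
        mat.to_csv(rpkm_path, sep="\t", float_format="%.6g")
        calls_path = out / "expression_calls.tsv"
        pd.DataFrame(
            {"detected": call.detected, "upregulated": call.upregulated_in_target}
        ).to_csv(calls_path, sep="\t")
        outputs = [rpkm_path, calls_path]
        if cfg.qpcr is not None and Path(cfg.qpcr).exists():
            q = qpcr_relative_expression(
                dio.read_ct_table(cfg.qpcr), "18S", cfg.reference_condition,
                tiers=cfg.qpcr_tiers,
            )
            qp = out / "qpcr_summary.tsv"
            q.summary.to_csv(qp, sep="\t", index=False, float_format="%.6g")
            outputs.append(qp)
        report.record("expression", True, {"reference": cfg.reference_condition},
                      outputs=outputs)
    else:
        report.record("expression", False)

    # ---- specificity ------------------------------------------------------
    all_sites = {}  # audit channel: every merged site, any label
    candidate_sites = {}
    site_target_gene = {}
    if (
        cfg.gene_models is not None and Path(cfg.gene_models).exists()
        and cfg.peaks_dir is not None and Path(cfg.peaks_dir).exists()
    ):
        genes = dio.read_gene_models(cfg.gene_models)
        peaks = {
            ct: dio.read_bed(Path(cfg.peaks_dir) / f"{ct}.bed")
            for ct in cfg.panel.cell_types
            if (Path(cfg.peaks_dir) / f"{ct}.bed").exists()
        }
        rows = []
        bed_records = []
        for gene in genes:
            domain = define_locus_domain(gene, cfg.upstream, cfg.downstream)
            cands, audit = screen_locus(
                domain, peaks, cfg.panel, cfg.subdued_ratio,
                cfg.max_nontarget_presence,
            )
            for rec in audit:
                ann = annotate_position(rec.site.interval, gene, genes)
                rows.append(
                    {
                        "site_id": rec.site.site_id,
                        "chrom": rec.site.interval.chrom,
                        "start": rec.site.interval.start,
                        "end": rec.site.interval.end,
                        "label": rec.call.label,
                        "genic_context": ann.genic_context,
                        "tss_relation": ann.tss_relation,
                        "tss_distance": ann.signed_tss_distance,
                        **{
                            f"present_{ct}": int(rec.site.peak_presence[ct])
                            for ct in cfg.panel.cell_types
                        },
                    }
                )
            for rec in audit:
                all_sites[rec.site.site_id] = rec.site.interval
            for rec in cands:
                candidate_sites[rec.site.site_id] = rec.site.interval
                site_target_gene[rec.site.site_id] = gene.gene_id
                bed_records.append(
                    (rec.site.interval, rec.site.site_id,
                     max(rec.site.peak_signal.values()))
                )
        sites_path = out / "sites.tsv"
        pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
        cand_path = out / "candidates.bed"
        dio.write_bed(cand_path, bed_records)
        report.record(
            "specificity", True,
            {"subdued_ratio": cfg.subdued_ratio, "fdr": cfg.fdr_note},
            outputs=[sites_path, cand_path],
        )
    else:
        report.record("specificity", False)

    # ---- reporter ---------------------------------------------------------
    calls = []
    replay_df = None
    if cfg.replay_table is not None and Path(cfg.replay_table).exists():
        replay_df = ev.load_table1_fixture(cfg.replay_table)
        calls = ev.replay_calls(replay_df, cfg.target_line, cfg.control_lines)
        report.record("reporter", True, {"mode": "call-replay"})
    elif cfg.plate is not None and Path(cfg.plate).exists():
        plate = dio.read_plate(cfg.plate)
        calls = score_plate(
            plate, cfg.fold_threshold, cfg.alpha, cfg.target_line,
            cfg.control_lines,
        )
        calls_path = out / "enhancer_calls.tsv"
        pd.DataFrame(
            [
                {
                    "site_id": c.site_id,
                    "minP_fold": c.minP_fold,
                    "minP_enhancer": c.minP_enhancer,
                    "promoter_fold_pct": c.promoter_fold_pct,
                    "promoter_p_value": c.promoter_p_value,
                    **{f"promoter_{k}": v for k, v in c.promoter_enhancer.items()},
                    "erythroid_specific": c.erythroid_specific_enhancer,
                    "category": c.category,
                    "positive_control": c.is_positive_control,
                }
                for c in calls
            ]
        ).to_csv(calls_path, sep="\t", index=False, float_format="%.6g")
        report.record(
            "reporter", True,
            {"fold_threshold": cfg.fold_threshold, "alpha": cfg.alpha,
             "multiple_testing_correction": "none"},
            outputs=[calls_path],
        )
    else:
        report.record("reporter", False)

    # ---- evidence ---------------------------------------------------------
    evidence_records = []
    if replay_df is not None:
        evidence_records = ev.evidence_from_fixture(replay_df)
        report.record("evidence", True, {"mode": "call-replay"})
    elif cfg.tracks_dir is not None and Path(cfg.tracks_dir).exists() and all_sites:
        tdir = Path(cfg.tracks_dir)
        tracks = {
            name: dio.read_track_bed(tdir / f"{name}.bed")
            for name in ("conserved", "faire", "h3k4me1", "h3k27ac", "gata1", "nfe2")
            if (tdir / f"{name}.bed").exists()
        }
        evidence_records = [
            ev.annotate_evidence(sid, iv, tracks)
            for sid, iv in all_sites.items()
        ]
        outputs = []
        tf_path = tdir / "tf_clusters.bed"
        if tf_path.exists():
            clusters = dio.read_track_bed(tf_path)
            matrix = ev.build_tf_matrix(candidate_sites, clusters, cfg.target_line)
            if (
                cfg.k <= matrix.frame.shape[0]
                and cfg.k <= matrix.frame.shape[1]
                and matrix.frame.size > 0
            ):
                matrix = ev.kmeans_classes(matrix, cfg.k, cfg.seed)
            mat_path = out / "tf_matrix.tsv"
            matrix.frame.to_csv(mat_path, sep="\t", float_format="%.2f")
            outputs.append(mat_path)
        report.record("evidence", True, {"k": cfg.k}, outputs=outputs)
    else:
        report.record("evidence", False)

    # ---- summary ----------------------------------------------------------
    scored = [c for c in calls if not c.is_positive_control]
    if scored or evidence_records:
        summary = ev.summarize_screen(scored, evidence_records,
                                      target_line=cfg.target_line)
    else:
        summary = ev.summarize_screen([], [])
    summary_path = dio.write_summary_json(out / "summary.json", summary.to_dict())
    report.record("summary", True, outputs=[summary_path])

    dio.write_summary_json(out / "run_report.json", report.to_dict())
    return report
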