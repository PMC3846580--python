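"""Synthetic inputs with planted ground truth for every pipeline stage.

One global seed fans out through ``numpy.random.SeedSequence.spawn`` to
independent per-component generators, so individual inputs can be
regenerated without disturbing the others. Noise models: log-normal
multiplicative noise on luciferase well ratios, normal noise on dCt,
Poisson read counts, log-normal peak signals.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .intervals import GenomicInterval, GeneModel, define_locus_domain
from .specificity import CellTypePanel, ERYTHROID_PANEL, roman
from .evidence import TrackElement

__all__ = ["SimulationConfig", "GroundTruthLedger", "SimulatedScreen",
           "simulate_screen", "emit_table1_fixture"]

SPECIFICITY_LABELS = ("target_specific", "putative_target_specific", "non_specific")
ENHANCER_CATEGORIES = ("non_enhancer", "minP_only", "promoter_only", "dual")
REPORTER_LINES = ("K562", "HeLa", "HEK293")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic screen. ``seed`` fully determines all outputs."""

    seed: int = 0
    n_genes: int = 10
    panel: CellTypePanel = ERYTHROID_PANEL
    sites_per_locus: int = 3
    # fractions of planted specificity classes; must sum to 1
    frac_target_specific: float = 0.4
    frac_putative: float = 0.3
    frac_ubiquitous: float = 0.3
    peak_signal_mean: float = 100.0
    peak_signal_sd_log: float = 0.3      # log-space sd of peak signals
    subdued_fraction: float = 0.2        # planted non-target / min target signal
    subdued_noise_sd_log: float = 0.25   # log-space noise on the subdued signal
    site_length: int = 400
    gene_length: int = 10_000
    upstream: int = 70_000
    downstream: int = 20_000
    # expression
    expression_baseline_rpkm: float = 5.0
    planted_fold: float = 3.0
    frac_upregulated: float = 0.5
    library_size: int = 2_000_000
    # qPCR
    qpcr_replicates: int = 3
    dct_noise_sd: float = 0.15
    # luciferase
    fold_by_category: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # (minP fold over baseline, promoter fold over baseline in K562)
            "non_enhancer": (1.0, 1.0),
            "minP_only": (8.0, 1.0),
            "promoter_only": (1.0, 3.0),
            "dual": (8.0, 3.0),
        }
    )
    frac_erythroid_specific: float = 0.7  # of promoter-positive sites
    offtarget_promoter_fold: float = 3.0  # used when not erythroid specific
    well_cv: float = 0.10                 # log-normal sigma of well ratios
    batches: int = 2
    replicates: int = 3
    baseline_activity: float = 20.0
    # evidence planting probabilities, per specificity label
    evidence_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.5, "faire": 0.6, "h3k4me1": 0.9,
            "h3k27ac": 0.7, "gata1": 0.5, "nfe2": 0.2,
        }
    )
    prob_histone_target_specific: float = 0.5
    tf_score_high: float = 800.0
    tf_score_low: float = 150.0

    def __post_init__(self) -> None:
        total = self.frac_target_specific + self.frac_putative + self.frac_ubiquitous
        if abs(total - 1.0) > 1e-9:
            raise ValueError("specificity fractions must sum to 1")
        if self.well_cv < 0:
            raise ValueError("well CV must be >= 0")
        min_span = self.sites_per_locus * (self.site_length + 200)
        if min_span > self.upstream + self.gene_length + self.downstream:
            raise ValueError("domain too short for the requested site spacing")


@dataclass
class GroundTruthLedger:
    """Planted truth for every generated entity."""

    gene_upregulated: pd.Series          # gene_id -> bool
    site_specificity: pd.Series          # site_id -> planted label
    site_category: pd.Series             # site_id -> planted enhancer category
    site_erythroid_specific: pd.Series   # site_id -> bool
    site_evidence: pd.DataFrame          # site_id x evidence booleans/flags

    def counts(self) -> dict:
        return {
            "n_genes": int(len(self.gene_upregulated)),
            "n_upregulated": int(self.gene_upregulated.sum()),
            "n_sites": int(len(self.site_specificity)),
            "specificity": self.site_specificity.value_counts().to_dict(),
            "category": self.site_category.value_counts().to_dict(),
            "n_erythroid_specific": int(self.site_erythroid_specific.sum()),
        }


@dataclass
class SimulatedScreen:
    """Everything simulate_screen produces, plus writers for the on-disk
    formats the real pipeline reads."""

    config: SimulationConfig
    genes: list[GeneModel]
    chrom_lengths: Mapping[str, int]
    peaks_by_cell_type: Mapping[str, list[tuple[GenomicInterval, float]]]
    site_intervals: Mapping[str, GenomicInterval]  # planted site positions
    site_gene: Mapping[str, str]
    counts: CountMatrix
    ct_table: pd.DataFrame
    plate: pd.DataFrame
    tracks: Mapping[str, list[TrackElement]]
    tf_clusters: list[TrackElement]
    ledger: GroundTruthLedger

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit all inputs as BED/TSV files under ``outdir``; deterministic
        for a fixed config (byte-identical across runs)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        gm = out / "gene_models.tsv"
        with gm.open("w") as fh:
            fh.write("gene_id\tchrom\tstrand\tstart\tend\ttss\tpolya"
                     "\texon_starts\texon_ends\n")
            for g in self.genes:
                starts = ",".join(str(e.start) for e in g.exons)
                ends = ",".join(str(e.end) for e in g.exons)
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.interval.start}"
                    f"\t{g.interval.end}\t{g.tss}\t{g.polya_site}"
                    f"\t{starts}\t{ends}\n"
                )
        written.append(gm)

        peaks_dir = out / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for ct, peaks in self.peaks_by_cell_type.items():
            p = peaks_dir / f"{ct}.bed"
            with p.open("w") as fh:
                for iv, score in sorted(peaks, key=lambda t: (t[0].chrom, t[0].start)):
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak\t{score:.4f}\n")
            written.append(p)

        cm = out / "counts.tsv"
        with cm.open("w") as fh:
            samples = "\t".join(self.counts.sample_ids)
            fh.write(f"gene_id\tlength\t{samples}\n")
            conds = "\t".join(self.counts.conditions)
            fh.write(f"#condition\t-\t{conds}\n")
            libs = "\t".join(str(int(x)) for x in self.counts.total_mapped_reads)
            fh.write(f"#total_mapped_reads\t-\t{libs}\n")
            for i, g in enumerate(self.counts.gene_ids):
                row = "\t".join(str(int(c)) for c in self.counts.counts[i])
                fh.write(f"{g}\t{int(self.counts.gene_lengths[i])}\t{row}\n")
        written.append(cm)

        ct_path = out / "qpcr_ct.tsv"
        self.ct_table.to_csv(ct_path, sep="\t", index=False, float_format="%.6f")
        written.append(ct_path)

        plate_path = out / "plate.tsv"
        self.plate.to_csv(plate_path, sep="\t", index=False, float_format="%.6f")
        written.append(plate_path)

        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for name, elements in self.tracks.items():
            p = tracks_dir / f"{name}.bed"
            with p.open("w") as fh:
                for el in sorted(elements, key=lambda e: (e.interval.chrom, e.interval.start)):
                    flag = 1 if el.target_specific else 0
                    fh.write(
                        f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
                        f"\t{el.name or name}\t{el.score:.1f}\t{el.cell_type}\t{flag}\n"
                    )
            written.append(p)
        tf_path = tracks_dir / "tf_clusters.bed"
        with tf_path.open("w") as fh:
            for el in sorted(self.tf_clusters, key=lambda e: (e.interval.chrom, e.interval.start, e.name)):
                fh.write(
                    f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
                    f"\t{el.name}\t{el.score:.1f}\t{el.cell_type}\t0\n"
                )
        written.append(tf_path)

        ledger_path = out / "ledger.tsv"
        led = pd.DataFrame(
            {
                "specificity": self.ledger.site_specificity,
                "category": self.ledger.site_category,
                "erythroid_specific": self.ledger.site_erythroid_specific,
            }
        )
        led.index.name = "site_id"
        led.to_csv(ledger_path, sep="\t")
        written.append(ledger_path)
        return written


def _plant_labels(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> list[str]:
    return list(
        rng.choice(
            SPECIFICITY_LABELS,
            size=n,
            p=[cfg.frac_target_specific, cfg.frac_putative, cfg.frac_ubiquitous],
        )
    )


def _simulate_peaks(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    site_iv: GenomicInterval,
    label: str,
) -> dict[str, float]:
    """Peak signal per cell type for one planted site (0 = absent)."""
    panel = cfg.panel
    signals = {ct: 0.0 for ct in panel.cell_types}
    base = cfg.peak_signal_mean
    target_sig = base * np.exp(
        rng.normal(0.0, cfg.peak_signal_sd_log, size=len(panel.target))
    )
    for ct, s in zip(panel.target, target_sig):
        signals[ct] = float(s)
    if label == "putative_target_specific":
        n_nt = int(rng.integers(1, 3))  # 1 or 2 non-target cell types
        chosen = rng.choice(len(panel.non_target), size=n_nt, replace=False)
        floor = min(target_sig)
        for idx in chosen:
            sub = cfg.subdued_fraction * floor * np.exp(
                rng.normal(0.0, cfg.subdued_noise_sd_log)
            )
            signals[panel.non_target[idx]] = float(sub)
    elif label == "non_specific":
        # ubiquitous: strong presence in >=3 non-target cell types
        n_nt = int(rng.integers(3, len(panel.non_target) + 1))
        chosen = rng.choice(len(panel.non_target), size=n_nt, replace=False)
        nt_sig = base * np.exp(rng.normal(0.0, cfg.peak_signal_sd_log, size=n_nt))
        for idx, s in zip(chosen, nt_sig):
            signals[panel.non_target[idx]] = float(s)
    return signals


def _simulate_plate_rows(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    site_id: str,
    gene_id: str,
    category: str,
    erythroid_specific: bool,
) -> list[dict]:
    """Wells for one site across promoters, cell lines and batches."""
    minp_fold, prom_fold = cfg.fold_by_category[category]
    prom_by_line = {"K562": prom_fold, "HeLa": 1.0, "HEK293": 1.0}
    if prom_fold > 1.0 and not erythroid_specific:
        line = "HeLa" if rng.random() < 0.5 else "HEK293"
        prom_by_line[line] = cfg.offtarget_promoter_fold
    rows = []
    def wells(construct, promoter, insert, cell_line, ratio):
        for batch in range(1, cfg.batches + 1):
            for rep in range(1, cfg.replicates + 1):
                renilla = 2.0
                noise = np.exp(rng.normal(0.0, cfg.well_cv))
                rows.append(
                    {
                        "construct_id": construct,
                        "promoter": promoter,
                        "insert": insert,
                        "cell_line": cell_line,
                        "batch": batch,
                        "replicate": rep,
                        "firefly": cfg.baseline_activity * ratio * noise * renilla,
                        "renilla": renilla,
                    }
                )
    wells(f"minP::{site_id}", "minP", site_id, "K562", minp_fold)
    for line in REPORTER_LINES:
        wells(f"{gene_id}P::{site_id}", f"{gene_id}P", site_id, line, prom_by_line[line])
    return rows


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate a complete synthetic screen with planted ground truth.

    Deterministic for a fixed config; see the module docstring for the
    noise models.
    """
    cfg = config
    root_ss = np.random.SeedSequence(cfg.seed)
    (ss_layout, ss_peaks, ss_counts, ss_qpcr, ss_plate, ss_evidence) = (
        root_ss.spawn(6)
    )
    rng_layout = np.random.default_rng(ss_layout)
    rng_peaks = np.random.default_rng(ss_peaks)
    rng_counts = np.random.default_rng(ss_counts)
    rng_qpcr = np.random.default_rng(ss_qpcr)
    rng_plate = np.random.default_rng(ss_plate)
    rng_ev = np.random.default_rng(ss_evidence)

    # --- gene models, one chromosome per locus ----------------------------
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    for i in range(cfg.n_genes):
        chrom = f"chr{i + 1}"
        chrom_lengths[chrom] = cfg.upstream + cfg.gene_length + cfg.downstream + 200_000
        strand = "+" if rng_layout.random() < 0.5 else "-"
        start = cfg.upstream + 50_000
        end = start + cfg.gene_length
        tss = start if strand == "+" else end - 1
        polya = end if strand == "+" else start
        n_ex = int(rng_layout.integers(2, 5))
        bounds = np.sort(
            rng_layout.choice(
                np.arange(start + 100, end - 100), size=2 * n_ex, replace=False
            )
        )
        exons = tuple(
            GenomicInterval(chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]))
            for j in range(n_ex)
            if bounds[2 * j] < bounds[2 * j + 1]
        )
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:03d}",
                interval=GenomicInterval(chrom, start, end, strand),
                tss=tss,
                polya_site=polya,
                exons=exons,
            )
        )

    # --- planted sites and per-cell-type peaks ----------------------------
    peaks_by_ct: dict[str, list[tuple[GenomicInterval, float]]] = {
        ct: [] for ct in cfg.panel.cell_types
    }
    site_intervals: dict[str, GenomicInterval] = {}
    site_gene: dict[str, str] = {}
    site_label: dict[str, str] = {}
    for gene in genes:
        dom = define_locus_domain(
            gene, cfg.upstream, cfg.downstream, chrom_lengths[gene.chrom]
        )
        labels = _plant_labels(rng_peaks, cfg.sites_per_locus, cfg)
        span = len(dom.interval) // cfg.sites_per_locus
        order = range(cfg.sites_per_locus)
        if gene.strand == "-":
            order = reversed(range(cfg.sites_per_locus))  # ids run 5'->3'
        for rank, slot in enumerate(order, start=1):
            jitter = int(rng_peaks.integers(0, max(span - cfg.site_length, 1)))
            s = dom.interval.start + slot * span + jitter
            iv = GenomicInterval(gene.chrom, s, s + cfg.site_length)
            sid = f"{gene.gene_id}-{roman(rank)}"  # matches screen_locus naming
            label = labels[slot]
            site_intervals[sid] = iv
            site_gene[sid] = gene.gene_id
            site_label[sid] = label
            for ct, sig in _simulate_peaks(rng_peaks, cfg, iv, label).items():
                if sig > 0:
                    peaks_by_ct[ct].append((iv, sig))

    # --- expression counts -------------------------------------------------
    target_samples = ("ESER", "FLER", "PBER")
    samples = ("HESC",) + target_samples
    conditions = samples
    gene_ids = tuple(g.gene_id for g in genes)
    lengths = np.array([len(g.interval) for g in genes], dtype=float)
    up = rng_counts.random(cfg.n_genes) < cfg.frac_upregulated
    lam = np.empty((cfg.n_genes, len(samples)))
    for j, smp in enumerate(samples):
        fold = np.where(up & (smp != "HESC"), cfg.planted_fold, 1.0)
        lam[:, j] = (
            cfg.expression_baseline_rpkm
            * fold
            * (lengths / 1e3)
            * (cfg.library_size / 1e6)
        )
    counts_mat = rng_counts.poisson(lam).astype(np.int64)
    totals = np.maximum(
        counts_mat.sum(axis=0), np.full(len(samples), cfg.library_size)
    )
    counts = CountMatrix(
        gene_ids=gene_ids,
        gene_lengths=lengths,
        sample_ids=samples,
        conditions=conditions,
        total_mapped_reads=totals.astype(float),
        counts=counts_mat,
    )

    # --- qPCR Ct table -----------------------------------------------------
    ct_rows = []
    ref_ct = 10.0
    for j, smp in enumerate(samples):
        for rep in range(1, cfg.qpcr_replicates + 1):
            ct_rows.append(
                {"gene": "18S", "sample": smp, "condition": conditions[j],
                 "replicate": rep, "ct": ref_ct + rng_qpcr.normal(0, 0.05)}
            )
    for i, gid in enumerate(gene_ids):
        base_dct = 12.0
        for j, smp in enumerate(samples):
            dct = base_dct
            if up[i] and smp != "HESC":
                dct -= np.log2(cfg.planted_fold)
            for rep in range(1, cfg.qpcr_replicates + 1):
                ct_rows.append(
                    {"gene": gid, "sample": smp, "condition": conditions[j],
                     "replicate": rep,
                     "ct": ref_ct + dct + rng_qpcr.normal(0, cfg.dct_noise_sd)}
                )
    ct_table = pd.DataFrame(ct_rows)

    # --- luciferase plate --------------------------------------------------
    site_ids = sorted(site_intervals)
    category: dict[str, str] = {}
    specific: dict[str, bool] = {}
    plate_rows: list[dict] = []
    # shared baselines per promoter and cell line
    def baseline_wells(construct, promoter, cell_line):
        for batch in range(1, cfg.batches + 1):
            for rep in range(1, cfg.replicates + 1):
                renilla = 2.0
                noise = np.exp(rng_plate.normal(0.0, cfg.well_cv))
                plate_rows.append(
                    {"construct_id": construct, "promoter": promoter,
                     "insert": "none", "cell_line": cell_line, "batch": batch,
                     "replicate": rep,
                     "firefly": cfg.baseline_activity * noise * renilla,
                     "renilla": renilla}
                )
    baseline_wells("minP", "minP", "K562")
    for gid in gene_ids:
        for line in REPORTER_LINES:
            baseline_wells(f"{gid}P", f"{gid}P", line)
    # positive control on minP at the threshold fold
    hs2_rng = rng_plate
    for batch in range(1, cfg.batches + 1):
        for rep in range(1, cfg.replicates + 1):
            renilla = 2.0
            noise = np.exp(hs2_rng.normal(0.0, cfg.well_cv))
            plate_rows.append(
                {"construct_id": "minP::HS2", "promoter": "minP",
                 "insert": "positive_control", "cell_line": "K562",
                 "batch": batch, "replicate": rep,
                 "firefly": cfg.baseline_activity * 5.0 * noise * renilla,
                 "renilla": renilla}
            )
    for sid in site_ids:
        cat = str(rng_plate.choice(ENHANCER_CATEGORIES))
        is_spec = bool(
            cat in ("promoter_only", "dual")
            and rng_plate.random() < cfg.frac_erythroid_specific
        )
        category[sid] = cat
        specific[sid] = is_spec
        plate_rows.extend(
            _simulate_plate_rows(rng_plate, cfg, sid, site_gene[sid], cat, is_spec)
        )
    plate = pd.DataFrame(plate_rows)

    # --- evidence tracks ---------------------------------------------------
    tracks: dict[str, list[TrackElement]] = {
        k: [] for k in ("conserved", "faire", "h3k4me1", "h3k27ac", "gata1", "nfe2")
    }
    ev_rows = []
    tf_clusters: list[TrackElement] = []
    tf_names = ("GATA1", "TAL1", "NFE2", "SP1", "JUND", "P300")
    for sid in site_ids:
        iv = site_intervals[sid]
        rec = {"site_id": sid}
        for track, prob in cfg.evidence_prob.items():
            hit = bool(rng_ev.random() < prob)
            rec[track] = hit
            if hit:
                # element kept inside the site so it cannot touch neighbors
                pad = int(rng_ev.integers(0, min(100, len(iv) // 4)))
                el_iv = GenomicInterval(iv.chrom, iv.start + pad, iv.end - pad)
                flag = False
                if track in ("h3k4me1", "h3k27ac"):
                    flag = bool(rng_ev.random() < cfg.prob_histone_target_specific)
                    rec[f"{track}_target_specific"] = flag
                tracks[track].append(
                    TrackElement(el_iv, name=track, cell_type="K562",
                                 target_specific=flag)
                )
            elif track in ("h3k4me1", "h3k27ac"):
                rec[f"{track}_target_specific"] = False
        ev_rows.append(rec)
        # TF clusters: enhancers attract high scores from more TFs
        strong = category[sid] in ("dual", "promoter_only")
        n_tf = int(rng_ev.integers(3, 6)) if strong else int(rng_ev.integers(0, 3))
        for name in rng_ev.choice(tf_names, size=n_tf, replace=False):
            score = cfg.tf_score_high if strong else cfg.tf_score_low
            score = float(np.clip(score * np.exp(rng_ev.normal(0, 0.1)), 0, 1000))
            tf_clusters.append(
                TrackElement(iv, name=str(name), score=score, cell_type="K562")
            )

    ledger = GroundTruthLedger(
        gene_upregulated=pd.Series(up, index=list(gene_ids)),
        site_specificity=pd.Series({s: site_label[s] for s in site_ids}),
        site_category=pd.Series(category),
        site_erythroid_specific=pd.Series(specific),
        site_evidence=pd.DataFrame(ev_rows).set_index("site_id"),
    )
    return SimulatedScreen(
        config=cfg,
        genes=genes,
        chrom_lengths=chrom_lengths,
        peaks_by_cell_type=peaks_by_ct,
        site_intervals=site_intervals,
        site_gene=site_gene,
        counts=counts,
        ct_table=ct_table,
        plate=plate,
        tracks=tracks,
        tf_clusters=tf_clusters,
        ledger=ledger,
    )


def emit_table1_fixture(path: str | Path) -> Path:
    """Write the packaged candidate-site call/evidence table to ``path``."""
    dest = Path(path)
    dest.parent.mkdir(parents=True, exist_ok=True)
    src = resources.files("dhscreen").joinpath("data/table1.tsv")
    with resources.as_file(src) as p:
        shutil.copyfile(p, dest)
    return dest
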