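"""Readers and writers for the plain-text formats the pipeline consumes.

BED is native (0-based half-open). The GTF-subset reader converts 1-based
closed coordinates on load. Every writer's output round-trips through the
matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evidence import TrackElement
from .expression import CountMatrix
from .intervals import GenomicInterval, GeneModel

__all__ = [
    "read_bed",
    "write_bed",
    "read_gene_models",
    "read_gtf_genes",
    "read_counts",
    "read_ct_table",
    "read_plate",
    "read_track_bed",
    "write_summary_json",
]


class FormatError(ValueError):
    """Malformed input file; message carries file and line."""


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """BED3+ with an optional name (col 4) and score (col 5)."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            score = float(parts[4]) if len(parts) >= 5 else 0.0
            out.append((iv, score))
    return out


def write_bed(
    path: str | Path,
    records: Sequence[tuple[GenomicInterval, str, float]],
) -> Path:
    """Write (interval, name, score) triples as BED5."""
    p = Path(path)
    with p.open("w") as fh:
        for iv, name, score in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:.4f}\n")
    return p


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Tab-separated gene models.

    Columns: gene_id, chrom, strand, start, end, then either explicit
    ``tss``/``polya`` columns or none (derived from strand), then
    comma-separated ``exon_starts``/``exon_ends``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"gene_id", "chrom", "strand", "start", "end"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: gene model table needs columns {sorted(needed)}")
    genes = []
    for row in df.itertuples():
        start, end = int(row.start), int(row.end)
        iv = GenomicInterval(row.chrom, start, end, row.strand)
        tss = int(row.tss) if hasattr(row, "tss") and not pd.isna(row.tss) else (
            start if row.strand == "+" else end - 1
        )
        polya = int(row.polya) if hasattr(row, "polya") and not pd.isna(row.polya) else (
            end if row.strand == "+" else start
        )
        exons: tuple[GenomicInterval, ...] = ()
        if hasattr(row, "exon_starts") and isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(x) for x in row.exon_starts.split(",") if x]
            ends = [int(x) for x in row.exon_ends.split(",") if x]
            if len(starts) != len(ends):
                raise FormatError(f"{path}: {row.gene_id}: exon start/end mismatch")
            exons = tuple(
                GenomicInterval(row.chrom, s, e) for s, e in zip(starts, ends)
            )
        genes.append(GeneModel(row.gene_id, iv, tss, polya, exons))
    return genes


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Minimal GTF subset: ``gene`` and ``exon`` features with a ``gene_id``
    attribute. 1-based closed input converted to 0-based half-open."""
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = parts[:9]
            gid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gid = chunk.split(None, 1)[1].strip('"')
                    break
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = int(start1) - 1, int(end1)
            if feature == "gene":
                gene_rows[gid] = {"chrom": chrom, "start": start, "end": end,
                                  "strand": strand}
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append(
                    GenomicInterval(chrom, start, end)
                )
    genes = []
    for gid, rec in gene_rows.items():
        iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"])
        tss = iv.start if rec["strand"] == "+" else iv.end - 1
        polya = iv.end if rec["strand"] == "+" else iv.start
        exons = tuple(sorted(exon_rows.get(gid, []), key=lambda e: e.start))
        genes.append(GeneModel(gid, iv, tss, polya, exons))
    return genes


def read_counts(path: str | Path) -> CountMatrix:
    """Count matrix TSV as written by the simulator: header row of sample
    ids, ``#condition`` and ``#total_mapped_reads`` comment rows, then one
    row per gene with its length and counts."""
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "length"]:
            raise FormatError(f"{path}: first columns must be gene_id, length")
        samples = tuple(header[2:])
        conditions = None
        totals = None
        gene_ids, lengths, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#condition":
                conditions = tuple(parts[2:])
                continue
            if parts[0] == "#total_mapped_reads":
                totals = np.array([float(x) for x in parts[2:]])
                continue
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: column count mismatch")
            gene_ids.append(parts[0])
            lengths.append(float(parts[1]))
            rows.append([int(x) for x in parts[2:]])
    if conditions is None or totals is None:
        raise FormatError(f"{path}: missing #condition or #total_mapped_reads row")
    return CountMatrix(
        gene_ids=tuple(gene_ids),
        gene_lengths=np.array(lengths),
        sample_ids=samples,
        conditions=conditions,
        total_mapped_reads=totals,
        counts=np.array(rows, dtype=np.int64),
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "sample", "condition", "replicate", "ct"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: Ct table needs columns {sorted(needed)}")
    return df


def read_plate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"construct_id", "promoter", "insert", "cell_line", "batch",
              "replicate", "firefly", "renilla"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: plate table needs columns {sorted(needed)}")
    if (df["renilla"] <= 0).any():
        bad = df.index[df["renilla"] <= 0][0]
        raise FormatError(f"{path}: non-positive renilla at data row {bad}")
    return df


def read_track_bed(path: str | Path) -> list[TrackElement]:
    """BED4+ evidence track: chrom start end name score cell_type flag."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            score = float(parts[4]) if len(parts) >= 5 else 0.0
            cell_type = parts[5] if len(parts) >= 6 else ""
            flag = bool(int(parts[6])) if len(parts) >= 7 else False
            out.append(
                TrackElement(iv, name=parts[3], score=score,
                             cell_type=cell_type, target_specific=flag)
            )
    return out


def write_summary_json(path: str | Path, payload: dict) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with p.open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return p
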