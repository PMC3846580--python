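"""Evidence annotation: external track joins, the site x TF score matrix,
k-means classes, call replay from a boolean evidence/call table, and the
screen-level summary counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import GenomicInterval, PositionalAnnotation, overlaps
from .reporter import EnhancerCall, call_erythroid_specific, categorize_site

__all__ = [
    "EvidenceRecord",
    "TfScoreMatrix",
    "ScreenSummary",
    "annotate_evidence",
    "build_tf_matrix",
    "kmeans_classes",
    "summarize_screen",
    "load_table1_fixture",
    "replay_calls",
    "evidence_from_fixture",
]

HISTONE_STATES = ("absent", "present", "present_target_specific")


@dataclass(frozen=True)
class EvidenceRecord:
    """Boolean/flagged external evidence for one site."""

    site_id: str
    conserved: bool
    faire: bool
    h3k4me1: str  # absent | present | present_target_specific
    h3k27ac: str
    gata1: bool
    nfe2: bool

    def __post_init__(self) -> None:
        for name in ("h3k4me1", "h3k27ac"):
            if getattr(self, name) not in HISTONE_STATES:
                raise ValueError(f"{self.site_id}: bad {name} state")

    @property
    def histone_marked(self) -> bool:
        return self.h3k4me1 != "absent" or self.h3k27ac != "absent"

    @property
    def target_specific_marked(self) -> bool:
        return (
            self.h3k4me1 == "present_target_specific"
            or self.h3k27ac == "present_target_specific"
        )

    @property
    def tf_occupied(self) -> bool:
        return self.gata1 or self.nfe2


@dataclass(frozen=True)
class TrackElement:
    """One element of an evidence track (BED4+-style)."""

    interval: GenomicInterval
    name: str = ""
    score: float = 0.0
    cell_type: str = ""
    target_specific: bool = False


def _any_overlap(site: GenomicInterval, elements: Iterable[TrackElement]) -> bool:
    return any(overlaps(site, el.interval) for el in elements)


def _histone_state(site: GenomicInterval, elements: Iterable[TrackElement]) -> str:
    state = "absent"
    for el in elements:
        if not overlaps(site, el.interval):
            continue
        if el.target_specific:
            return "present_target_specific"
        state = "present"
    return state


def annotate_evidence(
    site_id: str,
    site: GenomicInterval,
    tracks: Mapping[str, Sequence[TrackElement]],
) -> EvidenceRecord:
    """Join evidence tracks onto one site by half-open overlap.

    ``tracks`` maps track names (``conserved``, ``faire``, ``h3k4me1``,
    ``h3k27ac``, ``gata1``, ``nfe2``) to element lists; an absent track
    yields an all-absent column. Histone fields upgrade to
    ``present_target_specific`` when any overlapping element carries the
    target-specificity flag.
    """
    return EvidenceRecord(
        site_id=site_id,
        conserved=_any_overlap(site, tracks.get("conserved", ())),
        faire=_any_overlap(site, tracks.get("faire", ())),
        h3k4me1=_histone_state(site, tracks.get("h3k4me1", ())),
        h3k27ac=_histone_state(site, tracks.get("h3k27ac", ())),
        gata1=_any_overlap(site, tracks.get("gata1", ())),
        nfe2=_any_overlap(site, tracks.get("nfe2", ())),
    )


@dataclass
class TfScoreMatrix:
    """Site x TF cluster-score matrix (scores in [0, 1000])."""

    frame: pd.DataFrame  # rows = site_ids, cols = TF names
    row_classes: pd.Series | None = None
    col_classes: pd.Series | None = None


def build_tf_matrix(
    sites: Mapping[str, GenomicInterval],
    tf_clusters: Sequence[TrackElement],
    cell_type: str,
    aggregate: str = "max",
) -> TfScoreMatrix:
    """Score matrix over sites and TF cluster tracks for one cell type.

    Entry (site, tf) is the max (or, behind config, sum) cluster score of
    that TF's elements overlapping the site in ``cell_type``; 0 when none.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    clusters = [el for el in tf_clusters if el.cell_type == cell_type]
    tf_names = sorted({el.name for el in clusters})
    mat = pd.DataFrame(
        0.0, index=list(sites.keys()), columns=tf_names, dtype=float
    )
    for sid, iv in sites.items():
        for el in clusters:
            if overlaps(iv, el.interval):
                if aggregate == "max":
                    mat.loc[sid, el.name] = max(mat.loc[sid, el.name], el.score)
                else:
                    mat.loc[sid, el.name] += el.score
    return TfScoreMatrix(frame=mat)


def _canonical_labels(labels: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Relabel clusters by descending cluster mean so output is seed-stable."""
    means = {}
    for lab in np.unique(labels):
        means[lab] = data[labels == lab].mean()
    order = sorted(means, key=lambda lab: -means[lab])
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in labels])


def kmeans_classes(
    matrix: TfScoreMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> TfScoreMatrix:
    """Cluster rows and columns independently with k-means (Lloyd).

    Labels are canonicalized by descending cluster mean score, so the same
    data and seed always yield the same labelling. ``k`` must not exceed
    the number of rows (resp. columns).
    """
    frame = matrix.frame
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > frame.shape[0] or k > frame.shape[1]:
        raise ValueError("k exceeds matrix dimension")
    X = frame.to_numpy(dtype=float)

    row_km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    col_km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X.T)
    row_labels = _canonical_labels(row_km.labels_, X)
    col_labels = _canonical_labels(col_km.labels_, X.T)
    return TfScoreMatrix(
        frame=frame,
        row_classes=pd.Series(row_labels, index=frame.index, name="class"),
        col_classes=pd.Series(col_labels, index=frame.columns, name="class"),
    )


@dataclass(frozen=True)
class ScreenSummary:
    """Counts over a screened site set, as reported by the summary stage."""

    n_sites: int
    n_minP_enhancers: int
    n_promoter_enhancers: int
    n_erythroid_specific: int
    n_conserved_specific: int
    n_histone_marked_specific: int
    n_target_specific_marked_specific: int
    n_tf_occupied_specific: int
    genic_context_hist: Mapping[str, int] = field(default_factory=dict)
    tss_relation_hist: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_minP_enhancers": self.n_minP_enhancers,
            "n_promoter_enhancers": self.n_promoter_enhancers,
            "n_erythroid_specific": self.n_erythroid_specific,
            "evidence_over_specific": {
                "conserved": self.n_conserved_specific,
                "histone_marked": self.n_histone_marked_specific,
                "target_specific_marked": self.n_target_specific_marked_specific,
                "tf_occupied": self.n_tf_occupied_specific,
            },
            "genic_context": dict(self.genic_context_hist),
            "tss_relation": dict(self.tss_relation_hist),
        }


def summarize_screen(
    calls: Sequence[EnhancerCall],
    evidence: Sequence[EvidenceRecord],
    positions: Mapping[str, PositionalAnnotation] | None = None,
    target_line: str = "K562",
) -> ScreenSummary:
    """Aggregate the decision-tree calls, evidence and positional
    annotations over a common set of site ids.

    Evidence counts (conservation, histone marks, asterisked marks, TF
    occupancy) are computed over the erythroid-specific enhancer subset
    only, matching the screen's reporting convention.
    """
    ev_by_id = {e.site_id: e for e in evidence}
    call_ids = {c.site_id for c in calls}
    if calls and evidence and call_ids != set(ev_by_id):
        raise ValueError("call and evidence site ids do not match")

    specific = [c for c in calls if c.erythroid_specific_enhancer]
    spec_ev = [ev_by_id[c.site_id] for c in specific] if ev_by_id else []

    genic_hist: dict[str, int] = {}
    tss_hist: dict[str, int] = {}
    if positions:
        if call_ids and set(positions) != call_ids:
            raise ValueError("position and call site ids do not match")
        for ann in positions.values():
            genic_hist[ann.genic_context] = genic_hist.get(ann.genic_context, 0) + 1
            tss_hist[ann.tss_relation] = tss_hist.get(ann.tss_relation, 0) + 1

    return ScreenSummary(
        n_sites=len(calls),
        n_minP_enhancers=sum(c.minP_enhancer for c in calls),
        n_promoter_enhancers=sum(
            bool(c.promoter_enhancer.get(target_line, False)) for c in calls
        ),
        n_erythroid_specific=len(specific),
        n_conserved_specific=sum(e.conserved for e in spec_ev),
        n_histone_marked_specific=sum(e.histone_marked for e in spec_ev),
        n_target_specific_marked_specific=sum(
            e.target_specific_marked for e in spec_ev
        ),
        n_tf_occupied_specific=sum(e.tf_occupied for e in spec_ev),
        genic_context_hist=genic_hist,
        tss_relation_hist=tss_hist,
    )


# ---------------------------------------------------------------------------
# Call replay: consume a transcribed boolean call/evidence table instead of
# raw wells and tracks, so the decision tree and summaries run on published
# calls alone.
# ---------------------------------------------------------------------------

_FLAG_COLS = (
    "cs", "faire", "h3k4me1", "h3k27ac", "gata1", "nfe2",
    "minp", "klfp_k562", "klfp_hela", "klfp_hek293",
)


def load_table1_fixture(path=None) -> pd.DataFrame:
    """Load the packaged candidate-site call/evidence table.

    Columns: gene, dhs_id, then flag columns with values ``-``, ``Y`` or
    ``Y*`` (the starred form only in the histone columns). ``site_id`` is
    derived as ``<gene>-<dhs_id>``.
    """
    if path is None:
        src = resources.files("dhscreen").joinpath("data/table1.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "dhs_id", *_FLAG_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"fixture missing columns {missing}")
    bad = ~df[list(_FLAG_COLS)].isin(["-", "Y", "Y*"]).all(axis=None)
    if bad:
        raise ValueError("fixture contains flags outside {-, Y, Y*}")
    df = df.copy()
    df["site_id"] = df["gene"] + "-" + df["dhs_id"]
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site ids in fixture")
    return df


def _histone_from_flag(flag: str) -> str:
    return {"-": "absent", "Y": "present", "Y*": "present_target_specific"}[flag]


def evidence_from_fixture(df: pd.DataFrame) -> list[EvidenceRecord]:
    """EvidenceRecords from the fixture's evidence columns."""
    return [
        EvidenceRecord(
            site_id=row.site_id,
            conserved=row.cs == "Y",
            faire=row.faire == "Y",
            h3k4me1=_histone_from_flag(row.h3k4me1),
            h3k27ac=_histone_from_flag(row.h3k27ac),
            gata1=row.gata1 == "Y",
            nfe2=row.nfe2 == "Y",
        )
        for row in df.itertuples()
    ]


def replay_calls(
    df: pd.DataFrame,
    target_line: str = "K562",
    control_lines: Sequence[str] = ("HeLa", "HEK293"),
) -> list[EnhancerCall]:
    """Run the decision tree on a pre-made boolean call table.

    The fixture publishes the calls, not the raw luminescence, so fold and
    p-value fields are not recomputable and are reported as NaN.
    """
    line_cols = {"K562": "klfp_k562", "HeLa": "klfp_hela", "HEK293": "klfp_hek293"}
    calls = []
    for row in df.itertuples():
        promoter = {
            line: getattr(row, col) == "Y" for line, col in line_cols.items()
        }
        minp = row.minp == "Y"
        calls.append(
            EnhancerCall(
                site_id=row.site_id,
                minP_fold=float("nan"),
                minP_enhancer=minp,
                promoter_fold_pct=float("nan"),
                promoter_p_value=float("nan"),
                promoter_enhancer=promoter,
                erythroid_specific_enhancer=call_erythroid_specific(
                    promoter, target_line, control_lines
                ),
                category=categorize_site(minp, promoter[target_line]),
            )
        )
    return calls
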