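"""Cell-type specificity classification of DHS candidates.

A site inside a locus domain is *target-specific* when its peak appears only
in target-group cell types, *putative target-specific* when it also appears
in at most ``max_nontarget_presence`` non-target cell types but at much
lower signal, and *non-specific* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import GenomicInterval, LocusDomain, merge_intervals, overlaps

__all__ = [
    "CellTypePanel",
    "DHSSite",
    "SpecificityCall",
    "classify_specificity",
    "screen_locus",
    "roman",
]

DEFAULT_SUBDUED_RATIO = 0.5
DEFAULT_MAX_NONTARGET = 2

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    """Roman numeral for a positive integer (site naming within a locus)."""
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class CellTypePanel:
    """Partition of the assayed cell types into target and non-target groups."""

    target: tuple[str, ...]
    non_target: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.target or not self.non_target:
            raise ValueError("panel needs >=1 target and >=1 non-target cell type")
        names = list(self.target) + list(self.non_target)
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique across groups")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return self.target + self.non_target


#: The panel used throughout the erythroid screen.
ERYTHROID_PANEL = CellTypePanel(
    target=("ESER", "FLER", "PBER", "K562"),
    non_target=("HESC", "GM12878", "hTH2", "HeLa", "HepG2", "CACO2", "BJ"),
)


@dataclass(frozen=True)
class DHSSite:
    """One candidate site with per-cell-type peak presence and signal."""

    site_id: str
    interval: GenomicInterval
    peak_presence: Mapping[str, bool]
    peak_signal: Mapping[str, float]

    def __post_init__(self) -> None:
        for ct, present in self.peak_presence.items():
            if present and self.peak_signal.get(ct, 0.0) <= 0.0:
                raise ValueError(
                    f"{self.site_id}: presence in {ct} requires positive signal"
                )


@dataclass(frozen=True)
class SpecificityCall:
    label: str  # target_specific | putative_target_specific | non_specific
    offending_cell_types: tuple[str, ...] = ()


def classify_specificity(
    site: DHSSite,
    panel: CellTypePanel,
    subdued_ratio: float = DEFAULT_SUBDUED_RATIO,
    max_nontarget_presence: int = DEFAULT_MAX_NONTARGET,
) -> SpecificityCall:
    """Classify one site against the panel.

    ``target_specific``: present in at least one target cell type and in no
    non-target cell type. ``putative_target_specific``: present in at least
    one target cell type and in 1..``max_nontarget_presence`` non-target
    cell types, every such non-target signal strictly below
    ``subdued_ratio`` times the weakest present-target signal.
    ``non_specific`` otherwise.

    Missing presence entries for any panel member raise ``KeyError``; no
    silent imputation.
    """
    if not 0.0 < subdued_ratio < 1.0:
        raise ValueError("subdued_ratio must be in (0, 1)")
    for ct in panel.cell_types:
        if ct not in site.peak_presence:
            raise KeyError(f"{site.site_id}: no presence entry for cell type {ct!r}")

    present_targets = [ct for ct in panel.target if site.peak_presence[ct]]
    present_nontargets = tuple(
        ct for ct in panel.non_target if site.peak_presence[ct]
    )

    if not present_targets:
        return SpecificityCall("non_specific", present_nontargets)
    if not present_nontargets:
        return SpecificityCall("target_specific", ())
    if len(present_nontargets) <= max_nontarget_presence:
        floor = min(site.peak_signal[ct] for ct in present_targets)
        if all(
            site.peak_signal[ct] < subdued_ratio * floor
            for ct in present_nontargets
        ):
            return SpecificityCall("putative_target_specific", present_nontargets)
    return SpecificityCall("non_specific", present_nontargets)


@dataclass(frozen=True)
class ScreenedSite:
    """A merged site plus its classification (audit channel record)."""

    site: DHSSite
    call: SpecificityCall


def screen_locus(
    domain: LocusDomain,
    peaks_by_cell_type: Mapping[str, Sequence[tuple[GenomicInterval, float]]],
    panel: CellTypePanel,
    subdued_ratio: float = DEFAULT_SUBDUED_RATIO,
    max_nontarget_presence: int = DEFAULT_MAX_NONTARGET,
) -> tuple[list[ScreenedSite], list[ScreenedSite]]:
    """Screen a locus domain for specific sites.

    Per-cell-type peaks falling inside the domain are unioned into maximal
    connected intervals; each merged site gets presence/signal per cell type
    (signal = max score of its overlapping peaks), a Roman-numeral id
    assigned 5'->3' in locus orientation, and a specificity call.

    Returns ``(candidates, audit)`` where candidates excludes non_specific
    sites and audit retains everything.
    """
    dom = domain.interval
    clipped: dict[str, list[tuple[GenomicInterval, float]]] = {}
    pooled: list[GenomicInterval] = []
    for ct in panel.cell_types:
        kept = [
            (iv, score)
            for iv, score in peaks_by_cell_type.get(ct, ())
            if overlaps(iv, dom)
        ]
        clipped[ct] = kept
        pooled.extend(iv for iv, _ in kept)

    merged = merge_intervals(pooled)
    if dom.strand == "-":
        merged = merged[::-1]  # number 5'->3' along the gene

    audit: list[ScreenedSite] = []
    candidates: list[ScreenedSite] = []
    for idx, iv in enumerate(merged, start=1):
        presence = {}
        signal = {}
        for ct in panel.cell_types:
            hits = [s for piv, s in clipped[ct] if overlaps(piv, iv)]
            presence[ct] = bool(hits)
            signal[ct] = max(hits) if hits else 0.0
        site = DHSSite(
            site_id=f"{domain.gene_id}-{roman(idx)}",
            interval=iv,
            peak_presence=presence,
            peak_signal=signal,
        )
        call = classify_specificity(
            site, panel, subdued_ratio, max_nontarget_presence
        )
        rec = ScreenedSite(site, call)
        audit.append(rec)
        if call.label != "non_specific":
            candidates.append(rec)
    return candidates, audit
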