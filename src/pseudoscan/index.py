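"""Disrupted-coding fraction and the discrete PseudoIndex erosion score.

The disrupted fraction is the share of reference-CDS positions rendered
non-coding by the called events, taken as a set union so that overlapping
consequences are never double-counted:

* everything at or downstream of the first disruptive frame-breaking event
  (frameshift or splice-site loss) — a broken frame corrupts the rest of the
  protein;
* everything at or downstream of the first disruptive premature stop;
* the positions of every absent exon.

A disruptive start-codon loss (non-default) disrupts the whole CDS. The
fraction is then binned onto the discrete 0-5 PseudoIndex scale; index 0 is
reserved for targets with no disruptive event at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PseudoIndexConfig
from .mapping import ExonPlacement
from .mutations import (
    EXON_ABSENT,
    FRAME_BREAKING_KINDS,
    PREMATURE_STOP,
    START_CODON_LOSS,
    CallResult,
    MutationEvent,
)
from .reference import GeneReference


@dataclass
class GeneStatus:
    """Per-target verdict: the events, the eroded fraction, and the 0-5 index."""

    target_id: str
    gene_id: str
    events: list[MutationEvent]
    disrupted_fraction: float
    pseudoindex: int
    n_exons_placed: int
    n_exons_total: int
    in_frame_indels: list[dict] = field(default_factory=list)


def disrupted_fraction(events: list[MutationEvent], ref: GeneReference) -> float:
    """Fraction of reference-CDS positions disrupted by the given events."""
    length = len(ref.cds)
    disrupted: set[int] = set()
    frame_breaks = [e.cds_pos for e in events if e.disruptive and e.kind in FRAME_BREAKING_KINDS]
    if frame_breaks:
        disrupted.update(range(min(frame_breaks), length))
    stops = [e.cds_pos for e in events if e.disruptive and e.kind == PREMATURE_STOP]
    if stops:
        disrupted.update(range(min(stops), length))
    for e in events:
        if e.kind == EXON_ABSENT:
            disrupted.update(range(e.cds_pos, min(e.cds_pos + e.length, length)))
        elif e.kind == START_CODON_LOSS and e.disruptive:
            disrupted.update(range(length))
    return len(disrupted) / length


def to_pseudoindex(
    fraction: float,
    events: list[MutationEvent],
    bins_cfg: PseudoIndexConfig | None = None,
) -> int:
    """Bin the disrupted fraction onto the 0-5 scale (0 = no disruptive event)."""
    if bins_cfg is None:
        bins_cfg = PseudoIndexConfig()
    if not any(e.disruptive for e in events):
        return 0
    for edge, idx in sorted(bins_cfg.bins):
        if fraction <= edge:
            return idx
    return max(idx for _, idx in bins_cfg.bins)


def summarize(
    placements: list[ExonPlacement],
    result: CallResult,
    ref: GeneReference,
    target_id: str,
    bins_cfg: PseudoIndexConfig | None = None,
) -> GeneStatus:
    fraction = disrupted_fraction(result.events, ref)
    return GeneStatus(
        target_id=target_id,
        gene_id=ref.gene_id,
        events=list(result.events),
        disrupted_fraction=fraction,
        pseudoindex=to_pseudoindex(fraction, result.events, bins_cfg),
        n_exons_placed=sum(1 for p in placements if p.placed),
        n_exons_total=ref.n_exons,
        in_frame_indels=list(result.in_frame_indels),
    )
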