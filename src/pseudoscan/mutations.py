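"""Call gene-inactivating mutations from selected exon placements.

Mutation classes: frameshift insertions/deletions (indel length not divisible
by 3), premature termination codons (frameshift-aware translation of the
reconstructed target coding stream), splice-site losses (non-canonical
donor/acceptor dinucleotides), absent exons, and start-codon loss. Every
event is anchored to a 0-based reference-CDS coordinate so events can be
compared across species.

Indel anchors are left-normalized against the reference exon (VCF-style left
alignment): co-optimal gap placements inside repeats all map to the same
anchor, which keeps cross-species sharing of the "same" frameshift honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .config import CallerConfig
from .mapping import ExonPlacement
from .reference import ExonRef, GeneReference, STOP_CODONS

FRAMESHIFT_INSERTION = "frameshift_insertion"
FRAMESHIFT_DELETION = "frameshift_deletion"
PREMATURE_STOP = "premature_stop"
SPLICE_DONOR_LOSS = "splice_donor_loss"
SPLICE_ACCEPTOR_LOSS = "splice_acceptor_loss"
EXON_ABSENT = "exon_absent"
START_CODON_LOSS = "start_codon_loss"

FRAME_BREAKING_KINDS = frozenset(
    {FRAMESHIFT_INSERTION, FRAMESHIFT_DELETION, SPLICE_DONOR_LOSS, SPLICE_ACCEPTOR_LOSS}
)


class MutationKey(NamedTuple):
    """Identity of a lesion for cross-species sharing."""

    kind: str
    exon_index: int
    cds_pos: int


@dataclass(frozen=True)
class MutationEvent:
    kind: str
    exon_index: int
    cds_pos: int  # 0-based position in the reference CDS
    length: int
    detail: str = ""
    disruptive: bool = True

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.kind, self.exon_index, self.cds_pos)


@dataclass
class CallResult:
    """Events plus the in-frame indels that are recorded but never inactivating."""

    events: list[MutationEvent]
    in_frame_indels: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# indels


def _left_normalize_deletion(ref_seq: str, start: int, length: int) -> int:
    while start > 0 and ref_seq[start - 1] == ref_seq[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(ref_seq: str, start: int, inserted: str) -> tuple[int, str]:
    while start > 0 and inserted and ref_seq[start - 1] == inserted[-1]:
        inserted = ref_seq[start - 1] + inserted[:-1]
        start -= 1
    return start, inserted


def call_indels(placement: ExonPlacement, exon: ExonRef) -> tuple[list[MutationEvent], list[dict]]:
    """Extract gap runs from one placed exon's alignment.

    Gaps in the exon row are insertions (extra target sequence), gaps in the
    target row deletions. Runs whose length is not a multiple of 3 become
    frameshift events anchored at the left-normalized reference position;
    in-frame runs are returned as plain records, not events.
    """
    if not placement.placed:
        raise ValueError("call_indels requires a placed exon")
    aln = placement.alignment
    events: list[MutationEvent] = []
    in_frame: list[dict] = []
    ref_off = 0  # exon bases consumed so far
    col = 0
    q, t = aln.aligned_exon, aln.aligned_target
    n = len(q)
    while col < n:
        if q[col] == "-":  # insertion run
            run_start = col
            while col < n and q[col] == "-":
                col += 1
            inserted = t[run_start:col]
            length = len(inserted)
            anchor, norm_seq = _left_normalize_insertion(exon.seq, ref_off, inserted)
            cds_pos = min(exon.cds_start + anchor, exon.cds_end - 1)
            if length % 3 != 0:
                events.append(
                    MutationEvent(FRAMESHIFT_INSERTION, exon.index, cds_pos, length, detail=norm_seq)
                )
            else:
                in_frame.append(
                    {"kind": "in_frame_insertion", "exon_index": exon.index,
                     "cds_pos": cds_pos, "length": length, "detail": norm_seq}
                )
        elif t[col] == "-":  # deletion run
            run_start_ref = ref_off
            while col < n and col < len(t) and t[col] == "-" and q[col] != "-":
                ref_off += 1
                col += 1
            length = ref_off - run_start_ref
            anchor = _left_normalize_deletion(exon.seq, run_start_ref, length)
            cds_pos = exon.cds_start + anchor
            deleted = exon.seq[anchor : anchor + length]
            if length % 3 != 0:
                events.append(
                    MutationEvent(FRAMESHIFT_DELETION, exon.index, cds_pos, length, detail=deleted)
                )
            else:
                in_frame.append(
                    {"kind": "in_frame_deletion", "exon_index": exon.index,
                     "cds_pos": cds_pos, "length": length, "detail": deleted}
                )
        else:
            ref_off += 1
            col += 1
    return events, in_frame


# ---------------------------------------------------------------------------
# premature stops


def _stop_guard_band(cds_len: int, cfg: CallerConfig) -> int:
    """Distance (nt) upstream of the terminal stop inside which a premature
    stop is flagged non-disruptive."""
    return max(int(cfg.terminal_frac * cds_len), cfg.terminal_nt)


def call_premature_stops(
    placements: list[ExonPlacement],
    ref: GeneReference,
    caller_cfg: CallerConfig | None = None,
) -> list[MutationEvent]:
    """Translate the reconstructed target coding stream and report early stops.

    The target coding stream is the concatenation of the ungapped target
    footprints of placed exons in exon order (absent exons skipped). Reading
    starts at the first placed exon's phase; because inserted target bases are
    part of the stream and deleted reference bases are not, the frame shifts
    exactly as a ribosome's would after each frameshift. Codons overlapping
    alignment gaps (insertion-derived bases, or an internal deletion/absent
    exon junction) are skipped rather than imputed. Every clean stop codon
    strictly upstream of the reference terminal stop is reported; stops inside
    the terminal guard band are flagged non-disruptive.
    """
    if caller_cfg is None:
        caller_cfg = CallerConfig()
    placed = [p for p in placements if p.placed]
    if not placed:
        return []
    # Stream of (target base, ref CDS pos or None, from_insertion) + break points.
    bases: list[tuple[str, int | None, bool]] = []
    breaks: set[int] = set()  # stream index i: a gap lies between bases i-1 and i
    prev_index = None
    for p in placed:
        exon = ref.exons[p.exon_index]
        if prev_index is not None and p.exon_index != prev_index + 1:
            breaks.add(len(bases))  # absent exon(s) skipped between footprints
        prev_index = p.exon_index
        ref_off = 0
        for qc, tc in zip(p.alignment.aligned_exon, p.alignment.aligned_target):
            if qc != "-" and tc != "-":
                bases.append((tc, exon.cds_start + ref_off, False))
                ref_off += 1
            elif qc == "-":
                bases.append((tc, None, True))
            else:
                breaks.add(len(bases))
                ref_off += 1

    first_phase = ref.exons[placed[0].exon_index].phase
    start = (3 - first_phase) % 3  # skip the partial codon at a mid-codon start
    cds_len = len(ref.cds)
    terminal_start = cds_len - 3
    guard = _stop_guard_band(cds_len, caller_cfg)
    events: list[MutationEvent] = []
    for k in range(start, len(bases) - 2, 3):
        b0, b1, b2 = bases[k], bases[k + 1], bases[k + 2]
        if b0[2] or b1[2] or b2[2]:
            continue  # codon contains inserted bases
        if (k + 1) in breaks or (k + 2) in breaks:
            continue  # a deletion or skipped exon interrupts the codon
        codon = b0[0] + b1[0] + b2[0]
        if codon not in STOP_CODONS:
            continue
        cds_pos = b0[1]
        if cds_pos is None or cds_pos >= terminal_start:
            continue
        exon_index = next(e.index for e in ref.exons if e.cds_start <= cds_pos < e.cds_end)
        disruptive = cds_pos < terminal_start - guard
        events.append(
            MutationEvent(PREMATURE_STOP, exon_index, cds_pos, 3, detail=codon, disruptive=disruptive)
        )
    return events


# ---------------------------------------------------------------------------
# splice losses, absent exons, start loss


def call_splice_losses(placements: list[ExonPlacement], ref: GeneReference) -> list[MutationEvent]:
    """Non-canonical dinucleotides at internal boundaries of placed exons."""
    events: list[MutationEvent] = []
    for p in placements:
        if not p.placed or p.splice is None:
            continue
        exon = ref.exons[p.exon_index]
        sp = p.splice
        if p.exon_index > 0 and not sp.acceptor_ok:
            events.append(
                MutationEvent(SPLICE_ACCEPTOR_LOSS, p.exon_index, exon.cds_start, 2,
                              detail=sp.acceptor_dinuc or "")
            )
        if p.exon_index < ref.n_exons - 1 and not sp.donor_ok:
            events.append(
                MutationEvent(SPLICE_DONOR_LOSS, p.exon_index, exon.cds_end - 1, 2,
                              detail=sp.donor_dinuc or "")
            )
    return events


def call_absent_exons(placements: list[ExonPlacement], ref: GeneReference) -> list[MutationEvent]:
    return [
        MutationEvent(EXON_ABSENT, p.exon_index, ref.exons[p.exon_index].cds_start,
                      len(ref.exons[p.exon_index]))
        for p in placements
        if not p.placed
    ]


def call_start_loss(
    placements: list[ExonPlacement],
    ref: GeneReference,
    disruptive: bool = False,
) -> list[MutationEvent]:
    """Report a changed canonical start codon when exon 0 is placed.

    The target triplet aligned to reference CDS positions 0-2 must be complete
    (three aligned A/C/G/T bases, no gaps); an absent first exon is covered by
    exon_absent instead.
    """
    if not ref.cds.startswith("ATG"):
        return []
    first = next((p for p in placements if p.exon_index == 0), None)
    if first is None or not first.placed:
        return []
    triplet = []
    ref_off = 0
    for qc, tc in zip(first.alignment.aligned_exon, first.alignment.aligned_target):
        if qc != "-":
            if ref_off < 3:
                if tc == "-":
                    return []  # start codon overlaps a deletion: incomplete
                triplet.append(tc)
            ref_off += 1
            if ref_off >= 3:
                break
    if len(triplet) < 3:
        return []
    observed = "".join(triplet)
    if observed == "ATG" or set(observed) - set("ACGT"):
        return []
    return [MutationEvent(START_CODON_LOSS, 0, 0, 3, detail=observed, disruptive=disruptive)]


# ---------------------------------------------------------------------------


def call_all(
    placements: list[ExonPlacement],
    ref: GeneReference,
    caller_cfg: CallerConfig | None = None,
) -> CallResult:
    """Union of all mutation classes, sorted by (cds_pos, kind, exon)."""
    if caller_cfg is None:
        caller_cfg = CallerConfig()
    events: list[MutationEvent] = []
    in_frame: list[dict] = []
    for p in placements:
        if p.placed:
            ev, inf = call_indels(p, ref.exons[p.exon_index])
            events.extend(ev)
            in_frame.extend(inf)
    events.extend(call_premature_stops(placements, ref, caller_cfg))
    events.extend(call_splice_losses(placements, ref))
    events.extend(call_absent_exons(placements, ref))
    events.extend(call_start_loss(placements, ref, disruptive=caller_cfg.start_loss_disruptive))
    events.sort(key=lambda e: (e.cds_pos, e.kind, e.exon_index))
    in_frame.sort(key=lambda r: (r["cds_pos"], r["kind"]))
    return CallResult(events=events, in_frame_indels=in_frame)
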