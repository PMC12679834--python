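"""Place reference exons in a target region and pick winners.

For each exon the whole scoring battery is run, splice-site conservation is
tested around every candidate footprint, and the winner is chosen by a
two-key sort: splice viability first, percent identity second (raw score,
then earliest footprint, break the remaining ties). Both strands of the
region are tried; the strand with the greater summed identity of placed
exons is kept for the whole gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import PairwiseAlignment, ScoringScheme, align_exon_battery, reverse_complement
from .config import RunConfig
from .reference import ExonRef, GeneReference

log = logging.getLogger(__name__)

DONORS = frozenset({"GT"})
DONORS_WITH_GC = frozenset({"GT", "GC"})
ACCEPTORS = frozenset({"AG"})


class RegionTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceCheck:
    """Conservation of the intron dinucleotides flanking a footprint.

    Gene-terminal sides (acceptor of the first exon, donor of the last) are
    not applicable: their flag is vacuously true and the dinucleotide null,
    so terminal exons are never penalized for lacking an intron.
    """

    donor_ok: bool
    acceptor_ok: bool
    donor_dinuc: str | None
    acceptor_dinuc: str | None

    @property
    def n_ok(self) -> int:
        return int(self.donor_ok) + int(self.acceptor_ok)


@dataclass
class ExonPlacement:
    exon_index: int
    alignment: PairwiseAlignment | None
    splice: SpliceCheck | None
    status: str  # "placed" | "absent"
    strand_used: str = "+"

    @property
    def placed(self) -> bool:
        return self.status == "placed"


def check_splice_sites(
    region: str,
    footprint: tuple[int, int],
    exon_index: int,
    n_exons: int,
    allow_gc_donor: bool = False,
) -> SpliceCheck:
    """Check the GT donor after / AG acceptor before a candidate footprint.

    Only internal gene boundaries are checked; a flanking dinucleotide that
    would fall outside the region fails its check.
    """
    start, end = footprint
    donors = DONORS_WITH_GC if allow_gc_donor else DONORS
    if exon_index == 0:
        acceptor_ok, acceptor_dinuc = True, None
    else:
        acceptor_dinuc = region[start - 2 : start] if start >= 2 else None
        acceptor_ok = acceptor_dinuc in ACCEPTORS
    if exon_index == n_exons - 1:
        donor_ok, donor_dinuc = True, None
    else:
        donor_dinuc = region[end : end + 2] if end + 2 <= len(region) else None
        donor_ok = donor_dinuc in donors
    return SpliceCheck(
        donor_ok=donor_ok,
        acceptor_ok=acceptor_ok,
        donor_dinuc=donor_dinuc,
        acceptor_dinuc=acceptor_dinuc,
    )


def select_placement(
    candidates: list[tuple[PairwiseAlignment, SpliceCheck]],
) -> tuple[PairwiseAlignment, SpliceCheck]:
    """Pick the winning candidate by (splice flags, identity, score).

    Splice viability dominates: a candidate with more satisfied splice flags
    beats any candidate with fewer, regardless of identity. Remaining ties go
    to the earliest footprint start, so the choice is deterministic.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    return max(
        candidates,
        key=lambda c: (c[1].n_ok, c[0].identity_pct, c[0].score, -c[0].target_start),
    )


def place_exon(
    exon: ExonRef,
    region: str,
    schemes: list[ScoringScheme],
    n_exons: int,
    min_identity: float = 65.0,
    allow_gc_donor: bool = False,
    strand_used: str = "+",
) -> ExonPlacement:
    """Run the battery for one exon and select a placement (or call it absent)."""
    alignments = align_exon_battery(exon.seq, region, schemes)
    candidates = [
        (aln, check_splice_sites(region, aln.footprint, exon.index, n_exons, allow_gc_donor))
        for aln in alignments
    ]
    best_aln, best_splice = select_placement(candidates)
    if best_aln.identity_pct < min_identity:
        return ExonPlacement(exon.index, None, None, "absent", strand_used)
    return ExonPlacement(exon.index, best_aln, best_splice, "placed", strand_used)


def _demote_overlaps(placements: list[ExonPlacement]) -> None:
    """Overlapping footprints of adjacent placed exons signal a duplicated or
    collapsed locus; demote the lower-identity exon to absent (logged)."""
    changed = True
    while changed:
        changed = False
        placed = [p for p in placements if p.placed]
        for a, b in zip(placed, placed[1:]):
            sa, ea = a.alignment.footprint
            sb, eb = b.alignment.footprint
            if sa < eb and sb < ea:
                loser = a if a.alignment.identity_pct < b.alignment.identity_pct else b
                log.warning(
                    "footprints of exons %d and %d overlap; demoting exon %d to absent",
                    a.exon_index, b.exon_index, loser.exon_index,
                )
                idx = placements.index(loser)
                placements[idx] = ExonPlacement(
                    loser.exon_index, None, None, "absent", loser.strand_used
                )
                changed = True
                break


def place_gene(ref: GeneReference, region: str, config: RunConfig | None = None) -> list[ExonPlacement]:
    """Place every exon of the reference in the region, on one consistent strand.

    Both the region and its reverse complement are tried; the orientation with
    the greater sum of placed-exon identities wins for all exons (mixed-strand
    placements are almost always alignment artifacts). Exon order along the
    region is not enforced, but overlapping adjacent footprints demote the
    lower-identity exon.
    """
    if config is None:
        config = RunConfig()
    if not region:
        raise ValueError("target region must be non-empty")
    if len(region) > config.align.max_region_len:
        raise RegionTooLargeError(
            f"region of {len(region)} nt exceeds align.max_region_len="
            f"{config.align.max_region_len}"
        )
    region = region.upper()
    schemes = config.align.scheme_objects()
    by_strand: dict[str, list[ExonPlacement]] = {}
    for strand, reg in (("+", region), ("-", reverse_complement(region))):
        by_strand[strand] = [
            place_exon(
                exon,
                reg,
                schemes,
                ref.n_exons,
                min_identity=config.exon.min_identity,
                allow_gc_donor=config.splice.allow_gc_donor,
                strand_used=strand,
            )
            for exon in ref.exons
        ]

    def strand_score(ps: list[ExonPlacement]) -> float:
        return sum(p.alignment.identity_pct for p in ps if p.placed)

    plus, minus = strand_score(by_strand["+"]), strand_score(by_strand["-"])
    placements = by_strand["+"] if plus >= minus else by_strand["-"]
    order = [p.exon_index for p in placements if p.placed]
    starts = [placements_by.alignment.target_start for placements_by in placements if placements_by.placed]
    if starts != sorted(starts):
        log.warning("placed exons %s are not colinear along the region (rearrangement?)", order)
    _demote_overlaps(placements)
    return placements
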