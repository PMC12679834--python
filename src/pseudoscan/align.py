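"""Semi-global exon-to-region alignment under an affine-gap scoring battery.

A reference exon is placed inside a (much longer) target genomic region by
global dynamic programming with free terminal gaps on the exon row only:
region overhangs on either side of the exon cost nothing, while the exon
itself must be aligned end to end. This "fit" (glocal) policy treats the exon
as an island in genomic context, which is what exon-by-exon pseudogene
screening needs — a local aligner would silently trim eroded exon ends, and a
fully global one would force the whole intron-bearing region into the
alignment.

The dynamic program is Gotoh's three-state affine-gap recursion with a fixed
tie order (diagonal > up > left, i.e. match state preferred over a gap in the
region row, preferred over a gap in the exon row), so results are bitwise
reproducible. A gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Seq import reverse_complement as _bio_revcomp

log = logging.getLogger(__name__)

GAP = "-"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4

_NEG = -(1 << 40)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch rewards and affine gap penalties (all integers).

    ``mismatch`` must score above a one-base gap (``gap_open + gap_extend``);
    otherwise single substitutions would be absorbed into gap pairs and the
    exon would not anchor cleanly.
    """

    match: int
    mismatch: int
    gap_open: int = -20
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= self.match:
            raise ValueError("mismatch penalty must be below the match reward")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mismatch <= self.gap_open + self.gap_extend:
            raise ValueError(
                "mismatch must score above a 1-nt gap (gap_open + gap_extend)"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.match, self.mismatch, self.gap_open, self.gap_extend)


#: Battery of match/mismatch schemes spanning permissive to strict mismatch
#: ratios around EMBOSS-style nucleotide defaults; gap penalties are the
#: EMBOSS 10 / 0.5 pair doubled to stay integral.
DEFAULT_SCHEMES: tuple[ScoringScheme, ...] = tuple(
    ScoringScheme(m, mm) for m, mm in [(1, -1), (1, -2), (1, -3), (2, -1), (2, -3), (4, -1)]
)


@dataclass
class PairwiseAlignment:
    """One exon placed in a region under one scoring scheme.

    ``aligned_exon``/``aligned_target`` cover the footprint only (the region
    span between the first and last aligned exon base); free terminal region
    overhangs are not part of the strings. ``identity_pct`` counts matches
    over all footprint columns, internal gap columns included, so indels
    depress identity. N never matches anything.
    """

    scheme: ScoringScheme
    aligned_exon: str
    aligned_target: str
    score: int
    identity_pct: float
    target_start: int
    target_end: int

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)

    def target_footprint_seq(self) -> str:
        """Ungapped target sequence under the exon footprint."""
        return self.aligned_target.replace(GAP, "")


def _encode(seq: str, what: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{what} sequence must be non-empty")
    if not seq.isupper():
        log.info("%s sequence contains lowercase (soft-masked?) bases; uppercasing", what)
        seq = seq.upper()
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"{what} sequence contains non-ACGTN characters: {bad}")
    return codes


@njit(cache=False)
def _gotoh_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    m = q.shape[0]
    n = t.shape[0]
    NEG = -(1 << 40)
    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in exon row (consumes region)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in region row (consumes exon)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)  # predecessor state: 0=M 1=Y 2=X
    pX = np.zeros((m + 1, n + 1), dtype=np.int8)
    pY = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0
    for j in range(1, n + 1):
        X[0, j] = 0  # free leading region overhang
        pX[0, j] = 2
    for i in range(1, m + 1):
        a = M[i - 1, 0] + gap_open + gap_extend
        b = Y[i - 1, 0] + gap_extend
        if a >= b:
            Y[i, 0] = a
            pY[i, 0] = 0
        else:
            Y[i, 0] = b
            pY[i, 0] = 1
        qi = q[i - 1]
        for j in range(1, n + 1):
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            # diagonal into M; tie order M > Y > X (diagonal > up > left)
            best = M[i - 1, j - 1]
            p = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 1
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            # gap states may follow one another (X<->Y), which keeps the
            # policy symmetric under joint reverse-complement
            best = M[i, j - 1] + gap_open + gap_extend
            p = 0
            if Y[i, j - 1] + gap_open + gap_extend > best:
                best = Y[i, j - 1] + gap_open + gap_extend
                p = 1
            if X[i, j - 1] + gap_extend > best:
                best = X[i, j - 1] + gap_extend
                p = 2
            X[i, j] = best
            pX[i, j] = p
            best = M[i - 1, j] + gap_open + gap_extend
            p = 0
            if Y[i - 1, j] + gap_extend > best:
                best = Y[i - 1, j] + gap_extend
                p = 1
            if X[i - 1, j] + gap_open + gap_extend > best:
                best = X[i - 1, j] + gap_open + gap_extend
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    return M, X, Y, pM, pX, pY


def _identity(aligned_exon: str, aligned_target: str) -> float:
    cols = len(aligned_exon)
    matches = 0
    for a, b in zip(aligned_exon, aligned_target):
        if a == b and a != GAP and a != "N":
            matches += 1
    return 100.0 * matches / cols


def align_exon(exon_seq: str, region: str, scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal semi-global alignment of one exon inside a genomic region.

    Terminal gaps in the exon row (region overhangs) are free; everything
    else follows the affine scheme. Always returns an alignment.
    """
    q = _encode(exon_seq, "exon")
    t = _encode(region, "region")
    return _align_encoded(exon_seq.upper(), region.upper(), q, t, scheme)


def _align_encoded(
    exon_seq: str, region: str, q: np.ndarray, t: np.ndarray, scheme: ScoringScheme
) -> PairwiseAlignment:
    m = len(exon_seq)
    M, X, Y, pM, pX, pY = _gotoh_fill(q, t, *scheme.as_tuple())
    # Final state: trailing region overhang is free, so take the best of the
    # last exon row over all region prefixes. Strict > keeps the smallest
    # footprint end on ties; M is preferred over Y at equal score.
    rowM = M[m, 1:]
    rowY = Y[m, 1:]
    row = np.maximum(rowM, rowY)
    best = int(row.max())
    bj = int(np.argmax(row == best)) + 1
    state = 0 if rowM[bj - 1] == best else 1

    i, j, st = m, bj, state
    qcols: list[str] = []
    tcols: list[str] = []
    while i > 0:
        if st == 0:  # match/mismatch column
            qcols.append(exon_seq[i - 1])
            tcols.append(region[j - 1])
            st = int(pM[i, j])
            i -= 1
            j -= 1
        elif st == 1:  # gap in region row
            qcols.append(exon_seq[i - 1])
            tcols.append(GAP)
            st = int(pY[i, j])
            i -= 1
        else:  # gap in exon row (internal; the free overhang ends the loop at i == 0)
            qcols.append(GAP)
            tcols.append(region[j - 1])
            st = int(pX[i, j])
            j -= 1
    target_start = j
    aligned_exon = "".join(reversed(qcols))
    aligned_target = "".join(reversed(tcols))
    return PairwiseAlignment(
        scheme=scheme,
        aligned_exon=aligned_exon,
        aligned_target=aligned_target,
        score=best,
        identity_pct=_identity(aligned_exon, aligned_target),
        target_start=target_start,
        target_end=bj,
    )


def align_exon_battery(
    exon_seq: str, region: str, schemes: list[ScoringScheme] | tuple[ScoringScheme, ...]
) -> list[PairwiseAlignment]:
    """Run every scheme in the battery; one alignment per scheme, order kept."""
    if not schemes:
        raise ValueError("scheme battery must be non-empty")
    q = _encode(exon_seq, "exon")
    t = _encode(region, "region")
    exon_seq = exon_seq.upper()
    region = region.upper()
    return [_align_encoded(exon_seq, region, q, t, s) for s in schemes]


def reverse_complement(seq: str) -> str:
    """Reverse complement (delegates to Biopython; N maps to N)."""
    return _bio_revcomp(seq)
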