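"""Build and validate the gene reference: ordered exons plus concatenated CDS.

A :class:`GeneReference` can be constructed either from a genome FASTA plus a
GFF3/GTF annotation (CDS features of one transcript, reverse-complemented and
reordered for minus-strand genes) or from a user-supplied pair of FASTA files
(full CDS + individual exon sequences in order). Coordinates follow the usual
convention: 1-based inclusive at the GFF/GTF boundary, 0-based half-open
everywhere inside the package.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO

from .align import reverse_complement

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


class GeneNotFoundError(ValueError):
    pass


class SequenceNotFoundError(ValueError):
    pass


class InconsistentReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class ExonRef:
    """One reference exon with its coordinates inside the CDS.

    ``phase`` is the codon offset at the exon start: 0 means the exon begins
    on a codon boundary, 1/2 mean one/two bases of the codon were already
    consumed by upstream exons.
    """

    index: int
    seq: str
    phase: int
    cds_start: int
    cds_end: int

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneReference:
    gene_id: str
    exons: tuple[ExonRef, ...]
    cds: str
    strand: str = "+"
    source: str = "fasta_pair"

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def make_reference(
    gene_id: str, exon_seqs: list[str], strand: str = "+", source: str = "fasta_pair"
) -> GeneReference:
    """Assemble a GeneReference from in-order exon sequences, checking invariants."""
    if not exon_seqs:
        raise InconsistentReferenceError("a gene needs at least one exon")
    exons = []
    off = 0
    for i, seq in enumerate(exon_seqs):
        seq = seq.upper()
        if not seq:
            raise InconsistentReferenceError(f"exon {i} is empty")
        exons.append(ExonRef(index=i, seq=seq, phase=off % 3, cds_start=off, cds_end=off + len(seq)))
        off += len(seq)
    cds = "".join(e.seq for e in exons)
    if len(cds) < 3:
        raise InconsistentReferenceError("CDS shorter than one codon")
    return GeneReference(gene_id=gene_id, exons=tuple(exons), cds=cds, strand=strand, source=source)


# ---------------------------------------------------------------------------
# FASTA I/O (plain or gzip/bgzip)


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered id -> sequence dict."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


# ---------------------------------------------------------------------------
# Annotation route


def _detect_dialect(path: str | Path) -> str:
    """GTF uses 'key "value";' attributes, GFF3 uses key=value."""
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            if re.search(r'\w+ +"', attrs):
                return "gtf"
            if "=" in attrs:
                return "gff3"
    raise ValueError(f"could not detect GFF3/GTF dialect of {path}")


def _cds_by_transcript(db, dialect: str, gene_id: str) -> dict[str, list]:
    """Group CDS features of the requested gene by transcript id."""
    out: dict[str, list] = {}
    for f in db.features_of_type("CDS"):
        if dialect == "gtf":
            gid = f.attributes.get("gene_id", [None])[0]
            tid = f.attributes.get("transcript_id", [None])[0]
        else:
            tid = f.attributes.get("Parent", [None])[0]
            gid = None
            if tid is not None:
                try:
                    parent = db[tid]
                    gid = parent.attributes.get("Parent", [None])[0] or parent.id
                except gffutils.FeatureNotFoundError:
                    gid = f.attributes.get("gene_id", [None])[0]
            if gid is None:
                gid = f.attributes.get("gene_id", [None])[0]
        if gid == gene_id and tid is not None:
            out.setdefault(tid, []).append(f)
    return out


def build_from_annotation(
    genome: str | Path,
    annotation: str | Path,
    gene_id: str,
    transcript_id: str | None = None,
) -> GeneReference:
    """Extract one transcript's CDS segments from a genome + GFF3/GTF annotation.

    When ``transcript_id`` is not given, the transcript with the longest total
    CDS is selected, ties broken by lexicographically smallest transcript id
    (the choice is logged). Minus-strand segments are reverse-complemented and
    returned in translation order.
    """
    dialect = _detect_dialect(annotation)
    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx = _cds_by_transcript(db, dialect, gene_id)
    if not by_tx:
        raise GeneNotFoundError(f"gene not found: {gene_id!r} has no CDS features in {annotation}")
    if transcript_id is None:
        lengths = {tid: sum(f.end - f.start + 1 for f in feats) for tid, feats in by_tx.items()}
        transcript_id = min(lengths, key=lambda t: (-lengths[t], t))
        if len(by_tx) > 1:
            log.info(
                "gene %s has %d transcripts; selected %s (longest CDS, %d nt)",
                gene_id, len(by_tx), transcript_id, lengths[transcript_id],
            )
    elif transcript_id not in by_tx:
        raise GeneNotFoundError(f"transcript not found: {transcript_id!r} for gene {gene_id!r}")

    feats = sorted(by_tx[transcript_id], key=lambda f: f.start)
    strands = {f.strand for f in feats}
    if len(strands) != 1 or strands <= {".", "?"}:
        raise InconsistentReferenceError(f"CDS features of {transcript_id} have no single strand")
    strand = strands.pop()

    sequences = read_fasta(genome)
    exon_seqs = []
    for f in feats:
        if f.seqid not in sequences:
            raise SequenceNotFoundError(f"sequence not found: {f.seqid!r} missing from {genome}")
        seq = sequences[f.seqid][f.start - 1 : f.end]  # GFF is 1-based inclusive
        if len(seq) != f.end - f.start + 1:
            raise SequenceNotFoundError(
                f"CDS {f.start}-{f.end} exceeds sequence {f.seqid} ({len(sequences[f.seqid])} nt)"
            )
        exon_seqs.append(seq)
    if strand == "-":
        exon_seqs = [reverse_complement(s) for s in reversed(exon_seqs)]
    total = sum(len(s) for s in exon_seqs)
    if total % 3 != 0:
        log.warning(
            "CDS of %s/%s has length %d, not a multiple of 3 (incomplete terminal codon?)",
            gene_id, transcript_id, total,
        )
    return make_reference(gene_id, exon_seqs, strand=strand, source="annotation")


# ---------------------------------------------------------------------------
# FASTA-pair route


_ORDINAL_RE = re.compile(r"_(\d+)$")


def build_from_fasta_pair(cds_path: str | Path, exons_path: str | Path) -> GeneReference:
    """Build from a full-CDS FASTA plus a multi-FASTA of individual exons.

    Exon order is taken from a trailing ``_<int>`` in each record id when all
    records carry one; otherwise file order is used (with a logged notice).
    """
    cds_records = read_fasta(cds_path)
    gene_id, cds = next(iter(cds_records.items()))
    if len(cds_records) > 1:
        log.warning("CDS FASTA %s has %d records; using the first (%s)", cds_path, len(cds_records), gene_id)
    exon_records = list(read_fasta(exons_path).items())
    ordinals = [_ORDINAL_RE.search(name) for name, _ in exon_records]
    if all(ordinals) and len({int(m.group(1)) for m in ordinals}) == len(exon_records):
        exon_records.sort(key=lambda kv: int(_ORDINAL_RE.search(kv[0]).group(1)))
    else:
        log.info("exon ids in %s carry no unique trailing _<int> ordinals; using file order", exons_path)
    exon_seqs = [seq for _, seq in exon_records]
    concat = "".join(exon_seqs)
    if concat != cds:
        limit = min(len(concat), len(cds))
        pos = next((k for k in range(limit) if concat[k] != cds[k]), limit)
        raise InconsistentReferenceError(
            f"exon/CDS inconsistency: concatenated exons diverge from CDS at position {pos} "
            f"(exon concat {len(concat)} nt, CDS {len(cds)} nt)"
        )
    return make_reference(gene_id, exon_seqs, source="fasta_pair")


# ---------------------------------------------------------------------------


def validate_reference(ref: GeneReference, min_exon_len: int = 10) -> list[str]:
    """Soft sanity checks; returns a list of human-readable warnings."""
    warnings: list[str] = []
    if not ref.cds.startswith("ATG"):
        warnings.append(f"CDS does not start with ATG (found {ref.cds[:3]})")
    if ref.cds[-3:] not in STOP_CODONS:
        warnings.append(f"CDS lacks a terminal stop codon (ends {ref.cds[-3:]})")
    n_codons = len(ref.cds) // 3
    for c in range(n_codons - 1):
        codon = ref.cds[3 * c : 3 * c + 3]
        if codon in STOP_CODONS:
            warnings.append(f"internal in-frame stop codon {codon} at codon {c} (CDS position {3 * c + 1})")
    for e in ref.exons:
        if len(e) < min_exon_len:
            warnings.append(f"short exon: exon {e.index} is only {len(e)} nt (alignment may be unreliable)")
    return warnings


def write_reference_pair(ref: GeneReference, cds_path: str | Path, exons_path: str | Path) -> None:
    """Write the reference back out as a CDS FASTA + exon multi-FASTA pair."""
    with open(cds_path, "w") as fh:
        fh.write(f">{ref.gene_id}\n")
        for k in range(0, len(ref.cds), 60):
            fh.write(ref.cds[k : k + 60] + "\n")
    with open(exons_path, "w") as fh:
        for e in ref.exons:
            fh.write(f">{ref.gene_id}_exon_{e.index}\n")
            for k in range(0, len(e.seq), 60):
                fh.write(e.seq[k : k + 60] + "\n")
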