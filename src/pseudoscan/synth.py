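"""Deterministic synthetic genes, toy genomes, and lesioned target regions.

This module is the test bed for the whole pipeline: it generates a random
multi-exon gene with canonical structure (ATG start, single terminal stop, no
internal in-frame stop, GT..AG introns), embeds it in flanking sequence, and
derives per-target regions carrying known injected lesions together with the
exact MutationEvents the pipeline is expected to call.

Randomness is keyed per (seed, target_id, lesion ordinal) so adding a target
or lesion never perturbs any other target's bytes. Expected indel anchors are
left-normalized exactly like the caller's, so truth and calls are comparable
in repeat contexts.

Lesion injection operates on plus-strand cases; minus-strand synthesis is
supported for exercising the annotation-based reference builder.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import reverse_complement
from .mutations import (
    EXON_ABSENT,
    FRAMESHIFT_DELETION,
    FRAMESHIFT_INSERTION,
    PREMATURE_STOP,
    SPLICE_ACCEPTOR_LOSS,
    SPLICE_DONOR_LOSS,
    START_CODON_LOSS,
    _left_normalize_deletion,
    _left_normalize_insertion,
)
from .reference import GeneReference, STOP_CODONS, make_reference

BASES = np.array(list("ACGT"))

LESION_KINDS = (
    "substitute_to_stop",
    "delete",
    "insert",
    "kill_donor",
    "kill_acceptor",
    "delete_exon",
    "mutate_start",
    "neutral_substitutions",
)


@dataclass
class ExpectedEvent:
    """What the pipeline should call for one injected lesion.

    ``expected=False`` marks lesions that must NOT produce an event (in-frame
    indels, neutral substitutions).
    """

    kind: str
    cds_pos: int  # 0-based, like MutationEvent
    detail: str = ""
    expected: bool = True


@dataclass
class Lesion:
    kind: str
    params: dict


@dataclass
class TargetCase:
    target_id: str
    region: str
    lesions: list[Lesion] = field(default_factory=list)
    truth: list[ExpectedEvent] = field(default_factory=list)
    #: (original genomic position, length delta) per indel lesion, for mapping
    #: original coordinates onto the edited region.
    shifts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticCase:
    seed: int
    ref: GeneReference
    genome: str
    gff3: str
    exon_coords: list[tuple[int, int]]  # 0-based half-open, plus-strand genome
    strand: str = "+"
    targets: dict[str, TargetCase] = field(default_factory=dict)


def _rng(*keys) -> np.random.Generator:
    ints = [k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(ints)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p)) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + internal non-stop codons + one terminal stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(str(rng.choice(list(STOP_CODONS))))
    return "".join(codons)


def make_gene(
    seed: int,
    n_exons: int = 3,
    exon_len_range: tuple[int, int] = (60, 150),
    intron_len_range: tuple[int, int] = (60, 200),
    gc: float = 0.5,
    flank: int = 150,
    gene_id: str = "gene1",
    strand: str = "+",
) -> SyntheticCase:
    """Generate one gene with genomic context; same seed, same bytes."""
    if not 2 <= n_exons <= 12:
        raise ValueError("n_exons must be in 2..12")
    rng = _rng(seed, "gene", gene_id)
    lens = [int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)) for _ in range(n_exons)]
    lens[-1] += (-sum(lens)) % 3
    cds = _random_cds(rng, sum(lens) // 3, gc)
    exon_seqs = []
    off = 0
    for L in lens:
        exon_seqs.append(cds[off : off + L])
        off += L
    introns = [
        "GT" + _random_seq(rng, int(rng.integers(intron_len_range[0], intron_len_range[1] + 1)) - 4, gc) + "AG"
        for _ in range(n_exons - 1)
    ]
    left = _random_seq(rng, flank, gc)
    right = _random_seq(rng, flank, gc)

    parts = [left]
    exon_coords = []
    pos = len(left)
    for i, ex in enumerate(exon_seqs):
        exon_coords.append((pos, pos + len(ex)))
        parts.append(ex)
        pos += len(ex)
        if i < n_exons - 1:
            parts.append(introns[i])
            pos += len(introns[i])
    parts.append(right)
    genome = "".join(parts)
    ref = make_reference(gene_id, exon_seqs, strand=strand, source="synthetic")

    if strand == "-":
        n = len(genome)
        genome = reverse_complement(genome)
        # keep translation-order indexing: exon i's coordinates, reflected
        exon_coords = [(n - e, n - s) for s, e in exon_coords]

    gff3 = _gff3_text(gene_id, exon_coords, ref, strand, len(genome))
    return SyntheticCase(
        seed=seed, ref=ref, genome=genome, gff3=gff3,
        exon_coords=exon_coords, strand=strand,
    )


def _gff3_text(gene_id, exon_coords, ref, strand, genome_len) -> str:
    """GFF3 with gene/mRNA/exon/CDS features (1-based inclusive coordinates)."""
    seqid = "chr1"
    tid = f"{gene_id}.t1"
    gene_start = min(s for s, _ in exon_coords) + 1
    gene_end = max(e for _, e in exon_coords)
    lines = [
        "##gff-version 3",
        f"##sequence-region {seqid} 1 {genome_len}",
        f"{seqid}\tsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={gene_id};Name={gene_id}",
        f"{seqid}\tsynth\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={tid};Parent={gene_id}",
    ]
    # exon order in the file follows genomic coordinates
    order = sorted(range(len(exon_coords)), key=lambda i: exon_coords[i][0])
    for i in order:
        s, e = exon_coords[i]
        # translation-order index: exon_coords is indexed in translation order
        # for plus strand, genomic order equals translation order only on '+'.
        exon = ref.exons[i]
        gff_phase = (3 - exon.phase) % 3
        lines.append(
            f"{seqid}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tID={tid}.exon{i};Parent={tid}"
        )
        lines.append(
            f"{seqid}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{gff_phase}\tID={tid}.cds{i};Parent={tid}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# targets and lesions


def add_target(case: SyntheticCase, target_id: str) -> TargetCase:
    if case.strand != "+":
        raise ValueError("lesion targets are derived from plus-strand cases only")
    if target_id in case.targets:
        raise ValueError(f"duplicate target id {target_id!r}")
    tc = TargetCase(target_id=target_id, region=case.genome)
    case.targets[target_id] = tc
    return tc


def _cds_to_genomic(case: SyntheticCase, cds_pos: int) -> int:
    for exon, (gs, _) in zip(case.ref.exons, case.exon_coords):
        if exon.cds_start <= cds_pos < exon.cds_end:
            return gs + (cds_pos - exon.cds_start)
    raise ValueError(f"cds_pos {cds_pos} outside CDS")


def _exon_of(case: SyntheticCase, cds_pos: int):
    return next(e for e in case.ref.exons if e.cds_start <= cds_pos < e.cds_end)


def _map(tc: TargetCase, orig_pos: int) -> int:
    return orig_pos + sum(d for p, d in tc.shifts if p <= orig_pos)


def _edit(region: str, pos: int, new: str, old_len: int) -> str:
    return region[:pos] + new + region[pos + old_len :]


def inject(case: SyntheticCase, target_id: str, kind: str, **params) -> TargetCase:
    """Apply one lesion to a target's region and record the expected truth."""
    tc = case.targets[target_id]
    rng = _rng(case.seed, target_id, len(tc.lesions))
    ref = case.ref

    if kind == "substitute_to_stop":
        codon = int(params["codon"])
        if not 0 < codon < len(ref.cds) // 3 - 1:
            raise ValueError("codon must be internal")
        stop = str(rng.choice(list(STOP_CODONS)))
        for k in range(3):
            g = _map(tc, _cds_to_genomic(case, 3 * codon + k))
            tc.region = _edit(tc.region, g, stop[k], 1)
        tc.truth.append(ExpectedEvent(PREMATURE_STOP, 3 * codon, detail=stop))

    elif kind == "delete":
        cds_pos, length = int(params["cds_pos"]), int(params["length"])
        exon = _exon_of(case, cds_pos)
        if cds_pos + length > exon.cds_end:
            raise ValueError("deletion must stay within one exon")
        g = _map(tc, _cds_to_genomic(case, cds_pos))
        tc.region = _edit(tc.region, g, "", length)
        tc.shifts.append((_cds_to_genomic(case, cds_pos), -length))
        if length % 3 != 0:
            anchor = _left_normalize_deletion(exon.seq, cds_pos - exon.cds_start, length)
            tc.truth.append(ExpectedEvent(FRAMESHIFT_DELETION, exon.cds_start + anchor))
        else:
            tc.truth.append(ExpectedEvent("in_frame_deletion", cds_pos, expected=False))

    elif kind == "insert":
        cds_pos, length = int(params["cds_pos"]), int(params["length"])
        seq = params.get("seq") or _random_seq(rng, length)
        exon = _exon_of(case, cds_pos)
        g = _map(tc, _cds_to_genomic(case, cds_pos))
        tc.region = _edit(tc.region, g, seq, 0)
        tc.shifts.append((_cds_to_genomic(case, cds_pos), length))
        if length % 3 != 0:
            anchor, norm = _left_normalize_insertion(exon.seq, cds_pos - exon.cds_start, seq)
            tc.truth.append(ExpectedEvent(FRAMESHIFT_INSERTION, exon.cds_start + anchor, detail=norm))
        else:
            tc.truth.append(ExpectedEvent("in_frame_insertion", cds_pos, expected=False))

    elif kind == "kill_donor":
        exon_i = int(params["exon"])
        if exon_i >= ref.n_exons - 1:
            raise ValueError("last exon has no donor")
        new = str(rng.choice(["AT", "CT", "TT", "GA"]))
        g = _map(tc, case.exon_coords[exon_i][1])
        tc.region = _edit(tc.region, g, new, 2)
        tc.truth.append(ExpectedEvent(SPLICE_DONOR_LOSS, ref.exons[exon_i].cds_end - 1, detail=new))

    elif kind == "kill_acceptor":
        exon_i = int(params["exon"])
        if exon_i == 0:
            raise ValueError("first exon has no acceptor")
        new = str(rng.choice(["AC", "AA", "CG", "TG"]))
        g = _map(tc, case.exon_coords[exon_i][0] - 2)
        tc.region = _edit(tc.region, g, new, 2)
        tc.truth.append(ExpectedEvent(SPLICE_ACCEPTOR_LOSS, ref.exons[exon_i].cds_start, detail=new))

    elif kind == "delete_exon":
        exon_i = int(params["exon"])
        gs, ge = case.exon_coords[exon_i]
        g = _map(tc, gs)
        tc.region = _edit(tc.region, g, "", ge - gs)
        tc.shifts.append((gs, -(ge - gs)))
        tc.truth.append(ExpectedEvent(EXON_ABSENT, ref.exons[exon_i].cds_start))

    elif kind == "mutate_start":
        triplet = params.get("triplet") or str(rng.choice(["GTG", "ATA", "ACG", "TTG"]))
        if triplet == "ATG" or len(triplet) != 3:
            raise ValueError("triplet must be a non-ATG codon")
        g = _map(tc, _cds_to_genomic(case, 0))
        tc.region = _edit(tc.region, g, triplet, 3)
        tc.truth.append(ExpectedEvent(START_CODON_LOSS, 0, detail=triplet))

    elif kind == "neutral_substitutions":
        rate = float(params["rate"])
        _neutral_substitutions(case, tc, rng, rate)
        tc.truth.append(ExpectedEvent("neutral_substitutions", 0, expected=False))

    else:
        raise ValueError(f"unknown lesion kind {kind!r}; choose from {LESION_KINDS}")

    tc.lesions.append(Lesion(kind=kind, params=dict(params)))
    return tc


def _protected_positions(case: SyntheticCase) -> set[int]:
    """Genomic positions a neutral substitution must not touch: start codon,
    terminal stop, and the splice dinucleotides of every intron."""
    protected = set(range(_cds_to_genomic(case, 0), _cds_to_genomic(case, 0) + 3))
    last = len(case.ref.cds) - 3
    protected.update(_cds_to_genomic(case, last + k) for k in range(3))
    for i in range(case.ref.n_exons - 1):
        _, ge = case.exon_coords[i]
        gs_next, _ = case.exon_coords[i + 1]
        protected.update({ge, ge + 1, gs_next - 2, gs_next - 1})
    return protected


def _neutral_substitutions(case, tc: TargetCase, rng, rate: float) -> None:
    """Substitutions guaranteed not to create any callable event: no in-frame
    stop gains, no start/stop/splice changes."""
    protected = _protected_positions(case)
    exon_spans = list(zip(case.ref.exons, case.exon_coords))
    hits = np.flatnonzero(rng.random(len(case.genome)) < rate)
    for orig in map(int, hits):
        if orig in protected:
            continue
        cds_pos = None
        for exon, (gs, ge) in exon_spans:
            if gs <= orig < ge:
                cds_pos = exon.cds_start + (orig - gs)
                break
        cur = case.genome[orig]
        choices = [b for b in "ACGT" if b != cur]
        rng.shuffle(choices)
        new = None
        if cds_pos is None:
            new = choices[0]
        else:
            c = cds_pos // 3
            codon = list(case.ref.cds[3 * c : 3 * c + 3])
            for cand in choices:
                codon[cds_pos % 3] = cand
                if "".join(codon) not in STOP_CODONS:
                    new = cand
                    break
        if new is not None:
            g = _map(tc, orig)
            tc.region = _edit(tc.region, g, new, 1)


# ---------------------------------------------------------------------------
# canonical lesion battery


#: target id -> lesion kind for the standard single-lesion battery; t_clean
#: carries no lesion at all.
STANDARD_TARGETS = {
    "t_clean": None,
    "t_stop": "substitute_to_stop",
    "t_del": "delete",
    "t_ins": "insert",
    "t_donor": "kill_donor",
    "t_acceptor": "kill_acceptor",
    "t_exonloss": "delete_exon",
    "t_start": "mutate_start",
}


def make_standard_case(
    seed: int,
    n_exons: int = 3,
    exon_len_range: tuple[int, int] = (90, 150),
    intron_len_range: tuple[int, int] = (80, 150),
    flank: int = 120,
) -> SyntheticCase:
    """One gene + the eight canonical targets: clean, plus one per lesion class.

    Lesion coordinates are drawn per target within guard margins (6 nt from
    exon edges, stops confined to the 25-60% codon band) so every injected
    lesion has an unambiguous expected call.
    """
    case = make_gene(seed, n_exons=n_exons, exon_len_range=exon_len_range,
                     intron_len_range=intron_len_range, flank=flank)
    ref = case.ref
    n_codons = len(ref.cds) // 3
    for target_id, kind in STANDARD_TARGETS.items():
        add_target(case, target_id)
        if kind is None:
            continue
        rng = _rng(seed, target_id, "spec")
        if kind == "substitute_to_stop":
            codon = int(rng.integers(max(1, n_codons // 4), max(2, (n_codons * 3) // 5)))
            inject(case, target_id, kind, codon=codon)
        elif kind in ("delete", "insert"):
            length = int(rng.choice([1, 2, 4] if kind == "delete" else [1, 2]))
            exon = ref.exons[int(rng.integers(0, ref.n_exons))]
            lo, hi = exon.cds_start + 6, exon.cds_end - 6 - length
            cds_pos = int(rng.integers(lo, hi))
            inject(case, target_id, kind, cds_pos=cds_pos, length=length)
        elif kind == "kill_donor":
            inject(case, target_id, kind, exon=int(rng.integers(0, ref.n_exons - 1)))
        elif kind == "kill_acceptor":
            inject(case, target_id, kind, exon=int(rng.integers(1, ref.n_exons)))
        elif kind == "delete_exon":
            exon = 1 if ref.n_exons == 3 else int(rng.integers(1, ref.n_exons - 1))
            inject(case, target_id, kind, exon=exon)
        elif kind == "mutate_start":
            inject(case, target_id, kind)
    return case


# ---------------------------------------------------------------------------
# emission


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


def random_newick(seed: int, labels: list[str]) -> str:
    """Random coalescent-shaped binary topology over the labels."""
    rng = _rng(seed, "newick")
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1.0,{b}:1.0)")
    return nodes[0] + ";"


def emit(case: SyntheticCase, out_dir: str | Path) -> dict[str, Path]:
    """Write the case as plain-text files consumable by the pipeline CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "annotation.gff3",
        "targets": out / "targets.fasta",
        "cds": out / "ref_cds.fasta",
        "exons": out / "ref_exons.fasta",
        "truth": out / "truth.tsv",
        "newick": out / "targets.nwk",
    }
    _write_fasta(paths["genome"], [("chr1", case.genome)])
    paths["annotation"].write_text(case.gff3)
    _write_fasta(paths["targets"], [(tid, tc.region) for tid, tc in case.targets.items()])
    _write_fasta(paths["cds"], [(case.ref.gene_id, case.ref.cds)])
    _write_fasta(
        paths["exons"],
        [(f"{case.ref.gene_id}_exon_{e.index}", e.seq) for e in case.ref.exons],
    )
    with open(paths["truth"], "w") as fh:
        fh.write("target_id\tkind\tcds_pos\tdetail\texpected\n")
        for tid, tc in case.targets.items():
            for ev in tc.truth:
                fh.write(f"{tid}\t{ev.kind}\t{ev.cds_pos + 1}\t{ev.detail}\t{int(ev.expected)}\n")
    if case.targets:
        paths["newick"].write_text(random_newick(case.seed, list(case.targets)) + "\n")
    else:
        del paths["newick"]
    return paths
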