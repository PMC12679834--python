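"""End-to-end orchestration over many targets, with deterministic outputs.

The unit of concurrency is one target region (the cross-species use case:
one assembly per species). Results are gathered and written in input order,
so output bytes are identical regardless of worker count or completion
order. A pathological target is skipped with a logged reason instead of
aborting its siblings; only configuration/reference errors are fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import RunConfig
from .index import GeneStatus, summarize
from .mapping import ExonPlacement, place_gene
from .mutations import call_all
from .reference import GeneReference, read_fasta
from .tree import annotate_tree, export_annotated

log = logging.getLogger(__name__)


class DuplicateTargetError(ValueError):
    pass


@dataclass
class TargetResult:
    target_id: str
    status: GeneStatus | None = None
    placements: list[ExonPlacement] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunResult:
    results: list[TargetResult]
    out_dir: Path

    @property
    def statuses(self) -> list[GeneStatus]:
        return [r.status for r in self.results if r.status is not None]

    @property
    def skipped(self) -> dict[str, str]:
        return {r.target_id: r.error for r in self.results if r.error is not None}


def process_target(ref: GeneReference, target_id: str, region: str, config: RunConfig) -> TargetResult:
    """Align, call and summarize one target; exceptions become a soft skip."""
    try:
        placements = place_gene(ref, region, config)
        result = call_all(placements, ref, config.caller)
        status = summarize(placements, result, ref, target_id, config.pseudoindex)
        return TargetResult(target_id=target_id, status=status, placements=placements)
    except Exception as exc:  # soft-fail: one broken record must not kill a screen
        log.warning("target %s skipped: %s", target_id, exc)
        return TargetResult(target_id=target_id, error=str(exc))


def _process_star(args) -> TargetResult:
    return process_target(*args)


def run_pipeline(
    ref: GeneReference,
    targets: list[tuple[str, str]],
    config: RunConfig | None = None,
    out_dir: str | Path = "pseudoscan_out",
    newick: str | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> RunResult:
    """Run the full screen and write every output file.

    ``targets`` is an ordered list of (target_id, region sequence). Outputs:
    summary.tsv, mutations.tsv, per-target JSON under targets/, per-exon
    alignment text under alignments/, annotated.nwk + annotated.json when a
    newick is given, and run_manifest.json with input checksums.
    """
    if config is None:
        config = RunConfig()
    ids = [tid for tid, _ in targets]
    if len(set(ids)) != len(ids):
        dups = sorted({t for t in ids if ids.count(t) > 1})
        raise DuplicateTargetError(f"ambiguous target identifiers: {dups}")
    if not targets:
        raise ValueError("no target records")

    work = [(ref, tid, region, config) for tid, region in targets]
    if config.jobs > 1:
        with ProcessPoolExecutor(max_workers=config.jobs) as pool:
            results = list(pool.map(_process_star, work))
    else:
        results = [_process_star(w) for w in work]

    run = RunResult(results=results, out_dir=Path(out_dir))
    _write_outputs(run, ref, config, newick, input_paths or {})
    return run


# ---------------------------------------------------------------------------
# writers


def _fmt_float(x: float) -> str:
    return f"{x:.6f}"


def _event_dict(e) -> dict:
    return {
        "kind": e.kind,
        "exon_index": e.exon_index,
        "cds_pos": e.cds_pos + 1,  # reports are 1-based inclusive
        "length": e.length,
        "detail": e.detail,
        "disruptive": e.disruptive,
    }


def _placement_dict(p: ExonPlacement) -> dict:
    d: dict = {"exon_index": p.exon_index, "status": p.status, "strand": p.strand_used}
    if p.placed:
        a = p.alignment
        d.update(
            {
                "identity_pct": round(a.identity_pct, 4),
                "score": a.score,
                "target_start": a.target_start + 1,  # 1-based inclusive
                "target_end": a.target_end,
                "scheme": list(a.scheme.as_tuple()),
                "splice": {
                    "donor_ok": p.splice.donor_ok,
                    "acceptor_ok": p.splice.acceptor_ok,
                    "donor_dinuc": p.splice.donor_dinuc,
                    "acceptor_dinuc": p.splice.acceptor_dinuc,
                },
            }
        )
    return d


def _alignment_text(target_id: str, exon_index: int, p: ExonPlacement) -> str:
    """Three-row alignment blocks (exon / match line / target), 60 columns."""
    a = p.alignment
    lines = [
        f"# target={target_id} exon={exon_index} scheme={a.scheme.as_tuple()}",
        f"# identity={a.identity_pct:.2f}% score={a.score} "
        f"target={a.target_start + 1}..{a.target_end}",
    ]
    match_line = "".join(
        "|" if x == y and x != "-" and x != "N" else " "
        for x, y in zip(a.aligned_exon, a.aligned_target)
    )
    for k in range(0, len(a.aligned_exon), 60):
        lines.append("exon    " + a.aligned_exon[k : k + 60])
        lines.append("        " + match_line[k : k + 60])
        lines.append("target  " + a.aligned_target[k : k + 60])
        lines.append("")
    return "\n".join(lines)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(run: RunResult, ref, config, newick, input_paths) -> None:
    out = run.out_dir
    (out / "targets").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)
    cfg_echo = config.to_dict()

    with open(out / "summary.tsv", "w") as fh:
        fh.write("target_id\tpseudoindex\tdisrupted_fraction\tn_events\tn_exons_placed\n")
        for r in run.results:
            if r.status is None:
                continue
            s = r.status
            fh.write(
                f"{s.target_id}\t{s.pseudoindex}\t{_fmt_float(s.disrupted_fraction)}\t"
                f"{len(s.events)}\t{s.n_exons_placed}\n"
            )

    with open(out / "mutations.tsv", "w") as fh:
        fh.write("target_id\tgene_id\tkind\texon_index\tcds_pos\tlength\tdetail\tdisruptive\n")
        for r in run.results:
            if r.status is None:
                continue
            for e in r.status.events:
                fh.write(
                    f"{r.target_id}\t{ref.gene_id}\t{e.kind}\t{e.exon_index}\t"
                    f"{e.cds_pos + 1}\t{e.length}\t{e.detail}\t{str(e.disruptive).lower()}\n"
                )

    for r in run.results:
        if r.status is None:
            continue
        s = r.status
        doc = {
            "tool_version": __version__,
            "gene_id": s.gene_id,
            "target_id": s.target_id,
            "pseudoindex": s.pseudoindex,
            "disrupted_fraction": s.disrupted_fraction,
            "n_exons_placed": s.n_exons_placed,
            "n_exons_total": s.n_exons_total,
            "events": [_event_dict(e) for e in s.events],
            "in_frame_indels": [
                {**rec, "cds_pos": rec["cds_pos"] + 1} for rec in s.in_frame_indels
            ],
            "exons": [_placement_dict(p) for p in r.placements],
            "config": cfg_echo,
        }
        (out / "targets" / f"{s.target_id}.json").write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n"
        )
        for p in r.placements:
            if p.placed:
                (out / "alignments" / f"{s.target_id}_exon{p.exon_index}.txt").write_text(
                    _alignment_text(s.target_id, p.exon_index, p) + "\n"
                )

    if newick is not None:
        statuses = run.statuses
        atree = annotate_tree(newick, statuses, tree_cfg=config.tree)
        nwk, sidecar = export_annotated(atree)
        (out / "annotated.nwk").write_text(nwk)
        (out / "annotated.json").write_text(sidecar + "\n")

    manifest = {
        "tool_version": __version__,
        "gene_id": ref.gene_id,
        "n_targets": len(run.results),
        "target_order": [r.target_id for r in run.results],
        "skipped": run.skipped,
        "input_sha256": {name: _sha256(p) for name, p in sorted(input_paths.items())},
        "config": cfg_echo,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def export_exon_multifasta(
    results: list[TargetResult], exon_index: int, out_path: str | Path
) -> int:
    """Write the selected (ungapped) target sequences of one exon across targets.

    The records feed any downstream multiple-sequence aligner (e.g. a
    codon-aware MSA step); the pipeline itself never invokes one. Targets
    where the exon is absent are omitted with a logged notice. Returns the
    number of records written.
    """
    n = 0
    with open(out_path, "w") as fh:
        for r in results:
            p = next((p for p in r.placements if p.exon_index == exon_index), None)
            if p is None or not p.placed:
                log.info("exon %d absent in target %s; omitted from export", exon_index, r.target_id)
                continue
            seq = p.alignment.target_footprint_seq()
            fh.write(f">{r.target_id}_exon{exon_index}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
            n += 1
    return n
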