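"""Mutation calling on fixtures with known injected lesions."""

import pytest

from pseudoscan.config import CallerConfig, RunConfig
from pseudoscan.mapping import place_gene
from pseudoscan.mutations import (
    EXON_ABSENT,
    FRAMESHIFT_DELETION,
    FRAMESHIFT_INSERTION,
    PREMATURE_STOP,
    SPLICE_ACCEPTOR_LOSS,
    SPLICE_DONOR_LOSS,
    START_CODON_LOSS,
    call_all,
    call_indels,
    call_start_loss,
)
from pseudoscan.synth import add_target, inject, make_gene


def _calls(case, target_id, config):
    placements = place_gene(case.ref, case.targets[target_id].region, config)
    return placements, call_all(placements, case.ref, config.caller)


def test_clean_target_yields_no_events(standard_case, config):
    _, res = _calls(standard_case, "t_clean", config)
    assert res.events == []
    assert res.in_frame_indels == []


def test_perfect_exon_alignment_has_no_indels(standard_case, config):
    placements, _ = _calls(standard_case, "t_clean", config)
    ev, inframe = call_indels(placements[0], standard_case.ref.exons[0])
    assert ev == [] and inframe == []


@pytest.mark.parametrize(
    "target,kind",
    [
        ("t_stop", PREMATURE_STOP),
        ("t_del", FRAMESHIFT_DELETION),
        ("t_ins", FRAMESHIFT_INSERTION),
        ("t_donor", SPLICE_DONOR_LOSS),
        ("t_acceptor", SPLICE_ACCEPTOR_LOSS),
        ("t_exonloss", EXON_ABSENT),
        ("t_start", START_CODON_LOSS),
    ],
)
def test_each_lesion_class_is_recovered_at_expected_position(standard_case, config, target, kind):
    _, res = _calls(standard_case, target, config)
    truth = [t for t in standard_case.targets[target].truth if t.expected]
    called = {(e.kind, e.cds_pos) for e in res.events}
    for t in truth:
        assert (t.kind, t.cds_pos) in called
        assert t.kind == kind


def test_splice_loss_reports_observed_dinucleotide(standard_case, config):
    _, res = _calls(standard_case, "t_donor", config)
    ev = next(e for e in res.events if e.kind == SPLICE_DONOR_LOSS)
    truth = standard_case.targets["t_donor"].truth[0]
    assert ev.detail == truth.detail
    assert ev.detail not in ("GT", "")


def test_in_frame_deletion_is_recorded_but_not_an_event(config):
    case = make_gene(seed=33)
    add_target(case, "t")
    exon = case.ref.exons[1]
    inject(case, "t", "delete", cds_pos=exon.cds_start + 12, length=3)
    _, res = _calls(case, "t", config)
    assert res.events == []
    assert len(res.in_frame_indels) == 1
    assert res.in_frame_indels[0]["kind"] == "in_frame_deletion"
    assert res.in_frame_indels[0]["length"] == 3


def test_frameshift_induced_stops_are_dual_reported(config):
    """A frameshift early in the CDS produces both its own event and the
    downstream premature stops read in the shifted frame."""
    case = make_gene(seed=8)
    add_target(case, "t")
    inject(case, "t", "delete", cds_pos=case.ref.exons[0].cds_start + 30, length=1)
    _, res = _calls(case, "t", config)
    kinds = [e.kind for e in res.events]
    assert FRAMESHIFT_DELETION in kinds
    assert PREMATURE_STOP in kinds  # shifted frame hits a stop sooner or later
    fs = next(e for e in res.events if e.kind == FRAMESHIFT_DELETION)
    stops = [e for e in res.events if e.kind == PREMATURE_STOP]
    assert all(s.cds_pos > fs.cds_pos for s in stops)


def test_stop_near_terminus_is_flagged_non_disruptive(config):
    case = make_gene(seed=14)
    n_codons = len(case.ref.cds) // 3
    add_target(case, "t")
    inject(case, "t", "substitute_to_stop", codon=n_codons - 3)  # within 30 nt of the end
    _, res = _calls(case, "t", config)
    ev = next(e for e in res.events if e.kind == PREMATURE_STOP)
    assert not ev.disruptive


def test_start_loss_detail_and_default_nondisruptive(standard_case, config):
    placements, res = _calls(standard_case, "t_start", config)
    ev = next(e for e in res.events if e.kind == START_CODON_LOSS)
    assert ev.cds_pos == 0 and len(ev.detail) == 3 and ev.detail != "ATG"
    assert not ev.disruptive  # default: downstream ATG may rescue translation
    strict = call_start_loss(placements, standard_case.ref, disruptive=True)
    assert strict[0].disruptive


def test_absent_first_exon_suppresses_start_call(config):
    case = make_gene(seed=25, n_exons=4)
    add_target(case, "t")
    inject(case, "t", "delete_exon", exon=0)
    placements, res = _calls(case, "t", config)
    kinds = {e.kind for e in res.events}
    assert START_CODON_LOSS not in kinds
    assert any(e.kind == EXON_ABSENT and e.exon_index == 0 for e in res.events)


def test_events_are_sorted_and_deterministic(config):
    case = make_gene(seed=5)
    add_target(case, "t")
    inject(case, "t", "substitute_to_stop", codon=len(case.ref.cds) // 6)
    inject(case, "t", "kill_donor", exon=0)
    _, res1 = _calls(case, "t", config)
    _, res2 = _calls(case, "t", config)
    assert res1.events == res2.events
    positions = [e.cds_pos for e in res1.events]
    assert positions == sorted(positions)
    kinds = {e.kind for e in res1.events}
    assert SPLICE_DONOR_LOSS in kinds and PREMATURE_STOP in kinds


def test_zero_lesion_soundness_across_seeds(config):
    """Clean targets give zero events over many random genes (noise-free)."""
    for seed in range(40):
        case = make_gene(seed=seed)
        add_target(case, "t")
        _, res = _calls(case, "t", config)
        assert res.events == [], f"seed {seed}: {res.events}"


def test_neutral_substitutions_do_not_trigger_events(config):
    for seed in range(10):
        case = make_gene(seed=100 + seed)
        add_target(case, "t")
        inject(case, "t", "neutral_substitutions", rate=0.02)
        _, res = _calls(case, "t", config)
        assert res.events == [], f"seed {100 + seed}: {res.events}"
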