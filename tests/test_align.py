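"""Aligner unit and property tests against the pure-Python DP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pseudoscan.align import (
    DEFAULT_SCHEMES,
    ScoringScheme,
    align_exon,
    align_exon_battery,
    reverse_complement,
)

from _dp_oracle import oracle_align

SCHEME = ScoringScheme(1, -1, -2, -1)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def test_identical_sequences_align_perfectly():
    a = align_exon("ACGT", "ACGT", SCHEME)
    assert a.score == 4
    assert a.identity_pct == 100.0
    assert a.footprint == (0, 4)
    assert a.aligned_exon == a.aligned_target == "ACGT"


def test_exact_substring_is_found_with_free_overhangs():
    a = align_exon("ACGT", "TTTTACGTTTTT", SCHEME)
    assert a.identity_pct == 100.0
    assert a.footprint == (4, 8)
    assert a.score == 4  # overhangs cost nothing


def test_footprint_strings_reproduce_inputs():
    exon = "ACGTACGTACGTACGTACGT"
    region = "GG" + exon[:10] + "TTTTT" + exon[10:] + "CC"
    a = align_exon(exon, region, ScoringScheme(2, -3))
    assert a.aligned_exon.replace("-", "") == exon
    s, e = a.footprint
    assert a.aligned_target.replace("-", "") == region[s:e]
    assert len(a.aligned_exon) == len(a.aligned_target)
    assert 0 <= s < e <= len(region)


def test_n_bases_never_match():
    a = align_exon("NNNN", "NNNN", SCHEME)
    assert a.identity_pct == 0.0


def test_lowercase_input_is_uppercased():
    a = align_exon("acgt", "ttacgttt", SCHEME)
    assert a.identity_pct == 100.0
    assert a.aligned_exon == "ACGT"


@pytest.mark.parametrize("bad", ["", "ACGU", "ACG T"])
def test_invalid_sequences_are_rejected(bad):
    with pytest.raises(ValueError):
        align_exon(bad, "ACGT", SCHEME)


def test_empty_scheme_battery_is_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        align_exon_battery("ACGT", "ACGT", [])


def test_battery_preserves_scheme_order_and_is_deterministic():
    rng = np.random.default_rng(5)
    exon = "".join(rng.choice(list("ACGT"), 30))
    region = "".join(rng.choice(list("ACGT"), 80)) + exon + "".join(rng.choice(list("ACGT"), 40))
    res1 = align_exon_battery(exon, region, DEFAULT_SCHEMES)
    res2 = align_exon_battery(exon, region, DEFAULT_SCHEMES)
    assert [a.scheme for a in res1] == list(DEFAULT_SCHEMES)
    assert [(a.score, a.aligned_exon, a.aligned_target) for a in res1] == [
        (a.score, a.aligned_exon, a.aligned_target) for a in res2
    ]


def test_long_indel_recovered_as_single_gap():
    rng = np.random.default_rng(17)
    exon = "".join(rng.choice(list("ACGT"), 60))
    # target carries the exon with a 20-nt deletion in the middle
    region = "".join(rng.choice(list("ACGT"), 50)) + exon[:30] + exon[50:] + "".join(
        rng.choice(list("ACGT"), 50)
    )
    res = align_exon_battery(exon, region, DEFAULT_SCHEMES)
    assert any(a.aligned_target.count("-") == 20 and "-" * 20 in a.aligned_target for a in res)


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(0, -1)
    with pytest.raises(ValueError):
        ScoringScheme(1, 2)
    with pytest.raises(ValueError):
        ScoringScheme(1, -30, -20, -1)  # mismatch below a 1-nt gap


@settings(max_examples=50, derandomize=True)
@given(dna)
def test_self_alignment_identity_is_exactly_100(seq):
    for scheme in DEFAULT_SCHEMES:
        a = align_exon(seq, seq, scheme)
        assert a.identity_pct == 100.0
        assert a.footprint == (0, len(seq))


@settings(max_examples=100, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_reverse_complement_examples():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAAC") == "GTTT"


@settings(max_examples=30, derandomize=True)
@given(dna, st.text(alphabet="ACGT", min_size=1, max_size=100))
def test_score_symmetry_under_joint_reverse_complement(exon, region):
    for scheme in (SCHEME, ScoringScheme(2, -3)):
        fwd = align_exon(exon, region, scheme)
        rev = align_exon(reverse_complement(exon), reverse_complement(region), scheme)
        assert fwd.score == rev.score


def test_matches_oracle_on_embedded_exon_with_substitution(warm_aligner):
    rng = np.random.default_rng(3)
    exon = "".join(rng.choice(list("ACGT"), 30))
    mutated = exon[:14] + ("A" if exon[14] != "A" else "C") + exon[15:]
    region = (
        "".join(rng.choice(list("ACGT"), 90))
        + mutated
        + "".join(rng.choice(list("ACGT"), 80))
    )
    for scheme in DEFAULT_SCHEMES:
        got = align_exon(exon, region, scheme)
        score, identity, ts, te, ae, at = oracle_align(exon, region, *scheme.as_tuple())
        assert got.score == score
        assert got.identity_pct == identity
        assert got.footprint == (ts, te)


def test_matches_oracle_on_random_pairs(warm_aligner):
    """Implementation vs independent DP on 60 random small pairs, all schemes."""
    rng = np.random.default_rng(123)
    for _ in range(60):
        m = int(rng.integers(1, 41))
        n = int(rng.integers(m, 121))
        exon = "".join(rng.choice(list("ACGTN"), m, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        region = "".join(rng.choice(list("ACGT"), n))
        for scheme in DEFAULT_SCHEMES:
            got = align_exon(exon, region, scheme)
            score, identity, ts, te, ae, at = oracle_align(exon, region, *scheme.as_tuple())
            assert got.score == score, (exon, region, scheme)
            assert got.identity_pct == identity, (exon, region, scheme)
            assert (got.target_start, got.target_end) == (ts, te)
            assert (got.aligned_exon, got.aligned_target) == (ae, at)
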