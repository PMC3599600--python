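import pytest
from hypothesis import given, strategies as st

from armscan.motifs import (BUILTIN_PATTERNS, CK2, NES, NLS, MotifPattern,
                            find_tandem_repeats, parse_pattern,
                            phospho_proximity, PhosphoSite, scan_pattern)
from armscan.seqio import SequenceRecord
from armscan.stretches import ChargedStretch

from oracles import regex_extents

FRAGMENT = "GETTVDQRPDPVLDEGETTVDQRPDPVLDE"


def extents(seq, pattern):
    return {(h.start, h.end) for h in scan_pattern(seq, pattern)}


def test_parse_pattern_round_trip():
    pat = parse_pattern("NES", "L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]")
    assert pat.elements[0] == (frozenset("L"), 1, 1)
    assert pat.elements[1][1:] == (2, 3)
    assert pat.elements[2][0] == frozenset("LIVFM")
    assert pat.min_length == 9


def test_parse_pattern_rejects_garbage():
    with pytest.raises(ValueError, match="token"):
        parse_pattern("bad", "L-??-L")


def test_nes_minimal_spacer_match():
    assert extents("LAAVAALAL", NES) == {(1, 9)}


def test_nes_maximal_spacer_match():
    assert extents("LAAAFAAALAI", NES) == {(1, 11)}


def test_nls_literal_match():
    assert extents("ARKKRKDA", NLS) == {(2, 7)}


def test_ck2_on_printed_fragment():
    found = scan_pattern(FRAGMENT, CK2)
    assert [(h.start, h.matched) for h in found] == [(3, "TTVD"), (18, "TTVD")]
    # exhaustive 4-window oracle
    oracle = {
        (i + 1, i + 4)
        for i in range(len(FRAGMENT) - 3)
        if FRAGMENT[i] in "ST" and FRAGMENT[i + 3] in "DE"
    }
    assert extents(FRAGMENT, CK2) == oracle


@pytest.mark.parametrize("pattern", [NES, CK2, NLS], ids=["NES", "CK2", "NLS"])
@given(seq=st.text(alphabet="LAIVFMSTDEKRGQ", min_size=0, max_size=50))
def test_scanner_matches_regex_oracle(pattern, seq):
    assert extents(seq, pattern) == regex_extents(seq, pattern)


@given(st.text(alphabet="RKDAG", min_size=0, max_size=40))
def test_nls_is_exact_substring_search(seq):
    expected = set()
    start = seq.find("RKKRKD")
    while start != -1:
        expected.add((start + 1, start + 6))
        start = seq.find("RKKRKD", start + 1)
    assert extents(seq, NLS) == expected


@pytest.mark.parametrize(
    "site,stretch_span,distance,near",
    [(10, (12, 14), 2, True), (13, (12, 14), 0, True), (10, (20, 22), 10, False)],
)
def test_phospho_proximity_distances(site, stretch_span, distance, near):
    sites = [PhosphoSite("p", site, "S", "track")]
    stretches = [
        ChargedStretch("p", "negative", stretch_span[0], stretch_span[1], 3, "DDD")
    ]
    row = phospho_proximity(sites, stretches, window=5).iloc[0]
    assert row["distance"] == distance
    assert row["near"] == near


def test_phospho_proximity_reversal_symmetry():
    n = 40
    sites = [PhosphoSite("p", 10, "S", "x")]
    stretches = [ChargedStretch("p", "negative", 25, 29, 5, "DDDDD")]
    fwd = phospho_proximity(sites, stretches, 5).iloc[0]["distance"]
    sites_r = [PhosphoSite("p", n - 10 + 1, "S", "x")]
    stretches_r = [ChargedStretch("p", "negative", n - 29 + 1, n - 25 + 1, 5, "DDDDD")]
    rev = phospho_proximity(sites_r, stretches_r, 5).iloc[0]["distance"]
    assert fwd == rev


def test_tandem_repeat_simple_triplet():
    found = find_tandem_repeats("ACGACGACG", min_unit=3)
    assert len(found) == 1
    rep = found[0]
    assert (rep.unit_length, rep.copies, rep.min_identity) == (3, 3, 1.0)


def test_tandem_repeat_on_printed_fragment():
    found = find_tandem_repeats(FRAGMENT, min_unit=10)
    assert len(found) == 1
    rep = found[0]
    assert (rep.unit_length, rep.copies, rep.min_identity) == (15, 2, 1.0)
    assert rep.start == 1


def test_no_repeat_in_shuffled_background(rng):
    pool = list("GQTNASPEDKRLIV")
    seq = "".join(rng.choice(pool, size=250))
    assert find_tandem_repeats(seq, min_unit=10, min_identity=0.9) == []


def test_region_labels_agree_with_segmentation(mini_bundle, mini_annotations):
    from armscan.motifs import label_hits

    for rec in mini_bundle.records[:10]:
        found = label_hits(scan_pattern(rec, NES), mini_annotations)
        for h in found:
            assert h.region == mini_annotations[rec.id].region_of(h.start)
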