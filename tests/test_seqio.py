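import pandas as pd
import pytest

from armscan.seqio import (AnnotationTrack, CodingRecord, SeqioError,
                           SequenceRecord, join_metadata, pair_cds, read_fasta,
                           read_alignment, write_fasta)


def test_read_single_record(tmp_path):
    p = tmp_path / "one.fasta"
    p.write_text(">s1\nMKR\n")
    records = read_fasta(p)
    assert len(records) == 1
    assert records[0].id == "s1"
    assert records[0].residues == "MKR"


def test_duplicate_id_is_named_in_error(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">s1\nMK\n>s1\nRR\n")
    with pytest.raises(SeqioError, match="s1"):
        read_fasta(p)


def test_illegal_residue_reports_position():
    with pytest.raises(SeqioError, match="position 3"):
        SequenceRecord("s1", "MKZR")


def test_fasta_round_trip_is_byte_identical(tmp_path):
    seq = "MKRDEAGHILKNPQRSTVWYC" * 7  # forces 60-column wrapping
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta([SequenceRecord("long1", seq)], p1)
    write_fasta(read_fasta(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_clustal_and_fasta_alignment_dialects(tmp_path):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(">a\nMK-R\n>b\nMKAR\n")
    clustal = tmp_path / "aln.aln"
    clustal.write_text(
        "CLUSTAL W (1.83) multiple sequence alignment\n\n"
        "a    MK-R\nb    MKAR\n"
    )
    for path in (fasta, clustal):
        aln = read_alignment(path)
        assert aln.length == 4
        assert aln.ungapped("a") == "MKR"


@pytest.fixture()
def metadata_frame():
    return pd.DataFrame(
        {
            "id": ["s1", "s2", "s3"],
            "organism": ["orgA", "orgB", "orgC"],
            "family": ["F1", "F1", "F2"],
            "rank": [1, 2, 3],
        }
    )


def test_join_metadata_populates_all_fields(metadata_frame):
    records = [SequenceRecord(i, "MK") for i in ["s1", "s2", "s3"]]
    joined = join_metadata(records, metadata_frame)
    assert len(joined) == 3
    assert joined[0].organism == "orgA" and joined[0].rank == 1
    assert joined[2].family == "F2"


def test_join_metadata_drops_unmatched_records(metadata_frame, caplog):
    records = [SequenceRecord(i, "MK") for i in ["s1", "s2", "s9"]]
    joined = join_metadata(records, metadata_frame)
    assert [r.id for r in joined] == ["s1", "s2"]


def test_join_metadata_rejects_negative_rank(metadata_frame):
    metadata_frame.loc[0, "rank"] = -1
    with pytest.raises(SeqioError, match="non-negative"):
        join_metadata([SequenceRecord("s1", "MK")], metadata_frame)


def test_join_metadata_rejects_duplicate_table_id(metadata_frame):
    metadata_frame.loc[1, "id"] = "s1"
    with pytest.raises(SeqioError, match="collision"):
        join_metadata([SequenceRecord("s1", "MK")], metadata_frame)


@pytest.mark.parametrize(
    "cds,ok",
    [("ATGAAA", True), ("ATGAAG", True), ("ATGCCC", False)],
)
def test_pair_cds_translation_validation(cds, ok):
    prot = [SequenceRecord("p1", "MK")]
    coding = [CodingRecord("p1", cds)]
    if ok:
        pairs = pair_cds(prot, coding, validate=True)
        assert len(pairs) == 1
    else:
        with pytest.raises(SeqioError, match="codon 2"):
            pair_cds(prot, coding, validate=True)


def test_cds_length_must_frame():
    with pytest.raises(SeqioError, match="divisible by 3"):
        CodingRecord("p1", "ATGA")


def test_unmatched_cds_is_skipped_with_warning(caplog):
    pairs = pair_cds(
        [SequenceRecord("p1", "MK")],
        [CodingRecord("p1", "ATGAAA"), CodingRecord("ghost", "ATGAAA")],
    )
    assert [c.protein_id for _, c in pairs] == ["p1"]


def test_phospho_track_must_index_sty():
    rec = SequenceRecord("p1", "MSTAK")
    AnnotationTrack("p1", "phospho", phospho=frozenset({2, 3})).validate_against(rec)
    bad = AnnotationTrack("p1", "phospho", phospho=frozenset({5}))
    with pytest.raises(SeqioError, match="not S/T/Y"):
        bad.validate_against(rec)
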