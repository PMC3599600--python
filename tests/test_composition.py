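import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from armscan.composition import (composition_profile, consensus_disorder,
                                 disorder_enrichment, disorder_proxy,
                                 load_reference_freqs, load_scale)
from armscan.seqio import AnnotationTrack, SequenceRecord
from armscan.segmentation import RegionAnnotation


@pytest.mark.parametrize(
    "residues,expected",
    [("KRDE", 1.0), ("KRDEH", 0.8), ("AAAA", 0.0)],
)
def test_charged_fraction_uses_krde_only(residues, expected):
    prof = composition_profile(SequenceRecord("p", residues))
    assert prof.fraction_charged == pytest.approx(expected)


def test_x_residues_excluded_from_denominator():
    prof = composition_profile(SequenceRecord("p", "KRXX"))
    assert prof.fraction_charged == pytest.approx(1.0)


def test_empty_region_reports_missing_not_zero():
    rec = SequenceRecord("p", "MKRAAA")
    ann = RegionAnnotation("p", 6, core=(1, 6))  # no arms
    prof = composition_profile(rec, ann, "C")
    assert prof.missing
    assert prof.fraction_charged is None


def test_regional_charged_counts_sum_to_full(mini_bundle, mini_annotations):
    for rec in mini_bundle.records[:20]:
        ann = mini_annotations[rec.id]
        full = composition_profile(rec, ann, "full")
        total = 0
        for region in ("N", "core", "C"):
            prof = composition_profile(rec, ann, region)
            total += sum(prof.counts[aa] for aa in "KRDE")
        assert total == sum(full.counts[aa] for aa in "KRDE")


def test_enrichment_self_comparison_is_flat():
    ref = load_reference_freqs()
    counts = {row.residue: int(round(row.disordered * 10000))
              for row in ref.itertuples()}
    prof = composition_profile(SequenceRecord("p", "A"))  # replace counts below
    prof.counts.update(counts)
    enrich = disorder_enrichment(prof, ref, against="disordered")
    assert max(abs(v) for v in enrich.values()) < 0.05


def test_enrichment_poly_a_against_uniform():
    import pandas as pd

    uniform = pd.DataFrame(
        {"residue": list("ACDEFGHIKLMNPQRSTVWY"),
         "disordered": [0.05] * 20, "ordered": [0.05] * 20}
    )
    prof = composition_profile(SequenceRecord("p", "A" * 1000))
    enrich = disorder_enrichment(prof, uniform)
    assert enrich["A"] == pytest.approx(math.log2(20), abs=0.05)
    assert all(v < 0 for aa, v in enrich.items() if aa != "A")


def test_enrichment_requires_complete_reference():
    import pandas as pd

    partial = pd.DataFrame(
        {"residue": ["A"], "disordered": [1.0], "ordered": [1.0]}
    )
    prof = composition_profile(SequenceRecord("p", "AAAA"))
    with pytest.raises(ValueError, match="missing residues"):
        disorder_enrichment(prof, partial)


def test_disorder_proxy_extremes():
    scale = load_scale()
    top = max(scale, key=scale.get)     # strongest disorder promoter
    bottom = min(scale, key=scale.get)  # strongest order promoter
    assert disorder_proxy(SequenceRecord("p", top * 50)).fraction_disordered == 1.0
    assert disorder_proxy(SequenceRecord("p", bottom * 50)).fraction_disordered == 0.0


def test_disorder_proxy_window_one_is_pointwise():
    scale = load_scale()
    seq = "PWPWPW"  # P strongly disorder-promoting, W strongly order-promoting
    call = disorder_proxy(SequenceRecord("p", seq), window=1, threshold=0.0)
    expected = [scale[c] > 0 for c in seq]
    assert call.calls.tolist() == expected


def test_disorder_proxy_rejects_even_window():
    with pytest.raises(ValueError, match="odd"):
        disorder_proxy(SequenceRecord("p", "MKR"), window=4)


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
def test_disorder_proxy_reversal_covariance(seq):
    fwd = disorder_proxy(SequenceRecord("p", seq), window=5)
    rev = disorder_proxy(SequenceRecord("p", seq[::-1]), window=5)
    assert fwd.calls.tolist() == rev.calls.tolist()[::-1]


def test_full_fraction_is_length_weighted_mean(mini_bundle, mini_annotations):
    for rec in mini_bundle.records[:10]:
        ann = mini_annotations[rec.id]
        call = disorder_proxy(rec)
        acc = 0.0
        for region in ("N", "core", "C"):
            frac = call.region_fraction(ann, region)
            if frac is not None:
                acc += frac * ann.region_length(region)
        assert call.fraction_disordered == pytest.approx(acc / len(rec.residues))


def test_proxy_separates_arms_from_core(mini_bundle, mini_annotations):
    """Disorder-biased arms call mostly disordered, cores mostly ordered."""
    arm_fracs, core_fracs = [], []
    for rec in mini_bundle.records:
        ann = mini_annotations[rec.id]
        call = disorder_proxy(rec)
        core_fracs.append(call.region_fraction(ann, "core"))
        for region in ("N", "C"):
            frac = call.region_fraction(ann, region)
            if frac is not None and ann.region_length(region) >= 30:
                arm_fracs.append(frac)
    assert np.mean(arm_fracs) > 0.7
    assert np.mean(core_fracs) < 0.4


def _track(pid, bits):
    return AnnotationTrack(pid, "disorder", disorder=bits)


def test_consensus_modes():
    all_on = _track("p", "1111")
    all_off = _track("p", "0000")
    assert consensus_disorder([all_on, all_on]).calls.all()
    assert not consensus_disorder([all_on, all_off], "intersection").calls.any()
    assert consensus_disorder([all_on, all_off], "union").calls.all()


def test_consensus_length_mismatch_is_error():
    with pytest.raises(ValueError, match="length mismatch"):
        consensus_disorder([_track("p", "111"), _track("p", "11")])
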