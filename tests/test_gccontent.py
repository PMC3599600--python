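import numpy as np
import pytest

from armscan.gccontent import (classify_isochore, compare_slopes, fit_trend,
                               gc_profile, gene_vs_band, family_trends,
                               gc_table)
from armscan.seqio import CodingRecord, SequenceRecord
from armscan.segmentation import RegionAnnotation


def test_gc_profile_basic():
    prof = gc_profile((SequenceRecord("p", "MA"), CodingRecord("p", "ATGGCC")))
    assert prof.gc_full == pytest.approx(4 / 6)
    assert prof.gc3 == 1.0
    assert prof.gc1 == pytest.approx(0.5)


def test_gc_profile_at_only():
    prof = gc_profile((SequenceRecord("p", "II"), CodingRecord("p", "ATaTAT".upper())))
    assert prof.gc_full == 0.0


def test_regional_gc_weighted_mean_equals_full():
    ann = RegionAnnotation("p", 2, core=(2, 2), n_region=(1, 1))
    prof = gc_profile((SequenceRecord("p", "MA"), CodingRecord("p", "ATGGCC")), ann)
    assert prof.gc_n == pytest.approx(1 / 3)
    assert prof.gc_core == 1.0
    assert (3 * prof.gc_n + 3 * prof.gc_core) / 6 == pytest.approx(prof.gc_full)


def test_codon_position_conservation_random_cds(rng):
    for _ in range(50):
        n = int(rng.integers(1, 60)) * 3
        cds = "".join(rng.choice(list("ACGT"), size=n))
        prof = gc_profile(
            (SequenceRecord("p", "X" * (n // 3)), CodingRecord("p", cds))
        )
        assert prof.gc_full == pytest.approx((prof.gc1 + prof.gc2 + prof.gc3) / 3)


def test_fit_trend_exact_line():
    fit = fit_trend([(1, 10), (2, 12), (3, 14)])
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(8.0)
    assert fit.residual_se == pytest.approx(0.0, abs=1e-12)


def test_fit_trend_duplicated_point_keeps_slope():
    base = [(1.0, 10.0), (2.0, 12.0), (3.0, 14.0)]
    fit = fit_trend(base + [(2.0, 12.0)])
    assert fit.slope == pytest.approx(2.0)


def test_fit_trend_matches_closed_form(rng):
    for _ in range(25):
        x = rng.uniform(0, 50, size=20)
        y = rng.uniform(0, 100, size=20)
        fit = fit_trend(list(zip(x, y)))
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(ym - slope * xm, abs=1e-10)


def test_fit_trend_degenerate_x_is_error():
    with pytest.raises(ValueError, match="degenerate"):
        fit_trend([(1, 10), (1, 12)])


def test_compare_slopes_equal_gives_zero_z():
    a = fit_trend([(1, 10), (2, 12), (3, 14)], family="A")
    b = fit_trend([(1, 20), (2, 22), (3, 24)], family="B")
    tbl = compare_slopes([a, b])
    assert tbl.iloc[0]["z"] == 0.0


def test_compare_slopes_orders_by_angular_coefficient(rng):
    steep = [(x, 3.0 * x + rng.normal(0, 1)) for x in range(20)]
    flat = [(x, 0.3 * x + rng.normal(0, 1)) for x in range(20)]
    tbl = compare_slopes(
        [fit_trend(flat, family="flat"), fit_trend(steep, family="steep")]
    )
    assert tbl.iloc[0]["family_a"] == "steep"
    assert abs(tbl.iloc[0]["z"]) > 3


def test_compare_slopes_needs_two_fits():
    with pytest.raises(ValueError, match="at least two"):
        compare_slopes([fit_trend([(1, 1), (2, 2)])])


@pytest.mark.parametrize(
    "gc,label",
    [(37.1, "L"), (58.8, "H"), (43.0, "H1"), (0.0, "L"), (41.0, "H1"),
     (46.0, "H"), (100.0, "H")],
)
def test_isochore_classification(gc, label):
    assert classify_isochore(gc).label == label


def test_isochore_monotone():
    order = {"L": 0, "H1": 1, "H": 2}
    labels = [order[classify_isochore(g).label] for g in np.linspace(0, 100, 300)]
    assert labels == sorted(labels)


def test_isochore_out_of_range():
    with pytest.raises(ValueError):
        classify_isochore(104.0)


@pytest.mark.parametrize(
    "gene,band,concordant",
    [(58.8, 38.0, False), (47.4, 37.1, False), (44.0, 44.0, True)],
)
def test_gene_vs_band_concordance(gene, band, concordant):
    rec = gene_vs_band(gene, band)
    assert rec.concordant == concordant


def test_family_trend_recovers_generator_slope(mini_bundle, mini_annotations):
    from armscan.seqio import pair_cds

    pairs = pair_cds(mini_bundle.records, mini_bundle.cds)
    tbl = gc_table(pairs, mini_annotations)
    tbl["gc3_target"] = [
        mini_bundle.truth.gc3_targets[pid] for pid in tbl["protein_id"]
    ]
    # realised GC3 tracks the recorded target to codon-count resolution
    assert (tbl["gc3"] - tbl["gc3_target"]).abs().max() < 0.6
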