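import dataclasses
import filecmp

import numpy as np
import pytest

from armscan import motifs as mot
from armscan import stretches as strt
from armscan import synthetic as syn
from armscan.composition import DISORDER_PROMOTING
from armscan.seqio import pair_cds


def test_same_seed_is_byte_identical(tmp_path):
    cfg = syn.single_family_config(taxa=5, arm_length=60, with_features=True)
    a = syn.generate_family(cfg, seed=4).write(tmp_path / "a")
    b = syn.generate_family(cfg, seed=4).write(tmp_path / "b")
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), key


def test_different_seed_changes_output(tmp_path):
    cfg = syn.single_family_config(taxa=5, arm_length=60)
    a = syn.generate_family(cfg, seed=4).write(tmp_path / "a")
    b = syn.generate_family(cfg, seed=5).write(tmp_path / "b")
    assert not filecmp.cmp(a["proteins"], b["proteins"], shallow=False)


def test_zero_taxon_divergence_gives_identical_cores():
    cfg = syn.single_family_config(taxa=4, arm_length=40)
    cfg = dataclasses.replace(cfg, core_taxon_div=0.0)
    bundle = syn.generate_family(cfg, seed=8)
    cores = set()
    for rec in bundle.records:
        ann = bundle.truth.regions[rec.id]
        core = rec.residues[ann.core[0] - 1 : ann.core[1]]
        cores.add(core)
    # sanitisation may touch a handful of core sites; cores must agree at
    # nearly every position
    arrs = [np.array(list(c)) for c in cores]
    for other in arrs[1:]:
        assert (arrs[0] == other).mean() > 0.97


def test_manifest_completeness_zero_noise(mini_bundle):
    """Every planted feature is found, and nothing else is (precision=recall=1)."""
    truth = mini_bundle.truth
    for rec in mini_bundle.records:
        planted = {(f.start, f.end, f.name) for f in truth.features_of(rec.id, "stretch")}
        detected = {(s.start, s.end, s.sign) for s in strt.find_stretches(rec)}
        assert planted == detected
        for name in ("NES", "NLS"):
            planted_m = {
                (f.start, f.end)
                for f in truth.features_of(rec.id, "motif")
                if f.name == name
            }
            detected_m = {
                (h.start, h.end)
                for h in mot.scan_pattern(rec, mot.BUILTIN_PATTERNS[name])
            }
            assert planted_m == detected_m
        planted_r = {(f.start, f.end) for f in truth.features_of(rec.id, "repeat")}
        detected_r = {(r.start, r.end) for r in mot.find_tandem_repeats(rec)}
        assert planted_r == detected_r


def test_planted_repeat_has_seven_copies(mini_bundle):
    f1 = [r for r in mini_bundle.records if r.family == "F1"]
    for rec in f1:
        reps = mot.find_tandem_repeats(rec)
        assert len(reps) == 1
        assert reps[0].copies == 7
        assert reps[0].unit_length == 15
        assert reps[0].min_identity == 1.0


def test_arm_disorder_fraction_close_to_target():
    cfg = syn.single_family_config(taxa=12, arm_length=120, with_features=False)
    bundle = syn.generate_family(cfg, seed=6)
    target = cfg.arm_disorder_fraction
    for rec in bundle.records:
        ann = bundle.truth.regions[rec.id]
        for region in ("N", "C"):
            span = ann.region_span(region)
            if span is None or span[1] - span[0] + 1 < 100:
                continue
            arm = rec.residues[span[0] - 1 : span[1]]
            frac = sum(1 for c in arm if c in DISORDER_PROMOTING) / len(arm)
            assert abs(frac - target) <= 0.03


def test_cds_round_trips_through_translation(mini_bundle):
    pairs = pair_cds(mini_bundle.records, mini_bundle.cds, validate=True)
    assert len(pairs) == len(mini_bundle.records)


def test_infeasible_gc_target_raises():
    cfg = syn.single_family_config(taxa=3, arm_length=30, gc3_intercept=0.5,
                                   gc3_slope=0.0, gc3_noise_sd=0.0)
    with pytest.raises(syn.InfeasibleGCError, match="feasible interval"):
        syn.generate_family(cfg, seed=2)


def test_corrupt_rate_zero_is_identity(mini_bundle):
    assert syn.corrupt(mini_bundle, 0.0) is mini_bundle


def test_corrupt_records_survival_and_keeps_regions():
    cfg = syn.single_family_config(taxa=8, arm_length=80, with_features=True)
    bundle = syn.generate_family(cfg, seed=13)
    noisy = syn.corrupt(bundle, rate=0.05, seed=99)
    stretch_feats = [f for f in noisy.truth.features if f.kind == "stretch"]
    assert stretch_feats
    recall = sum(f.survived for f in stretch_feats) / len(stretch_feats)
    assert recall >= 0.8
    # destroyed arms lose their motifs almost surely
    wrecked = syn.corrupt(bundle, rate=1.0, seed=99)
    nes = [f for f in wrecked.truth.features if f.kind == "motif" and f.name == "NES"]
    assert sum(f.survived for f in nes) <= len(nes) * 0.2


def test_stretch_recall_under_moderate_noise():
    cfg = syn.single_family_config(taxa=6, arm_length=80, with_features=True)
    bundle = syn.generate_family(cfg, seed=17)
    survived = total = 0
    for rep in range(10):
        noisy = syn.corrupt(bundle, rate=0.05, seed=100 + rep)
        feats = [f for f in noisy.truth.features if f.kind == "stretch"]
        survived += sum(f.survived for f in feats)
        total += len(feats)
    assert survived / total >= 0.8
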