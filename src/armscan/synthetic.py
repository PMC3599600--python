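"""Synthetic family generator with a complete ground-truth manifest.

Emulates a sirtuin-like protein family: a conserved catalytic core evolving
by substitutions along a known class/family/taxon hierarchy, terminal arms
with disorder-biased composition and family-specific lengths, planted
charged stretches, localisation motifs, kinase sites and tandem repeats at
recorded coordinates, and in-frame coding sequences whose third-codon-
position GC follows a configurable linear trend in phylogenetic rank.

Arms are generated as suffixes (N side) / prefixes (C side) of per-class
ancestor arms, so the emitted alignment — arms padded as terminal blocks
around the fixed-length core — is the true alignment.  Background sequence
is sanitised against the feature detectors so that, at zero noise, every
detector hit is a planted feature: precision and recall are 1.0 by
construction, which is what makes the manifest a usable oracle.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import motifs as _motifs
from . import stretches as _stretches
from .seqio import (AlignmentBlock, CodingRecord, SequenceRecord,
                    write_alignment, write_fasta, write_metadata)
from .segmentation import RegionAnnotation

# ---------------------------------------------------------------------------
# Residue pools

#: disorder-promoting pool (positive TOP-IDP propensity) with draw weights
DP_POOL = "TAGRDHQSKEP"
DP_WEIGHTS = np.array([0.04, 0.06, 0.10, 0.08, 0.10, 0.02, 0.10, 0.14, 0.14, 0.16, 0.06])
#: order-promoting pool
ORDER_POOL = "WFYIMLVNC"
ORDER_WEIGHTS = np.array([0.03, 0.09, 0.07, 0.16, 0.05, 0.28, 0.18, 0.10, 0.04])

_DP_SET = frozenset(DP_POOL)
_NEUTRAL = "GNQTA"  # sanitisation replacements: uncharged, outside NES classes

NES_PLANT = "LNGVNGLNI"  # minimal-spacer NES instance
NLS_PLANT = "RKKRKD"
CK2_SINGLE = "TGQD"  # one CK2 acceptor (T) with acidic anchor
CK2_DOUBLE = "TTGDD"  # two overlapping CK2 acceptors (T1, T2)
REPEAT_UNIT = "GQTNAGPNQAGSPGN"  # 15 residues, motif- and stretch-free

_FLANK = 2  # neutral residues isolating planted features


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class FamilySpec:
    """Per-family arm geometry, planted features, and GC trend."""

    name: str
    n_mean: float
    n_sd: float
    c_mean: float
    c_sd: float
    n_stretches: tuple[str, ...] = ()  # signs of planted N-arm runs
    c_stretches: tuple[str, ...] = ()
    n_motifs: tuple[str, ...] = ()  # "NES" / "NLS"
    n_ck2_sites: int = 0  # CK2 acceptors planted right of the first N-arm negative runs
    c_repeat: Optional[tuple[int, int]] = None  # (unit_length, copies); unit_length 15
    gc3_intercept: float = 38.0  # percent at rank 0
    gc3_slope: float = 0.8  # percent per rank unit
    # junction offsets of the first planted block; families sharing an arm
    # class share an offset so planted columns align within, and only
    # within, the class
    n_offset: int = _FLANK
    c_offset: int = _FLANK
    # blocks beyond this count restart at the distal offset, keeping a short
    # class partner's comparison window free of family-private features
    n_proximal_blocks: Optional[int] = None
    n_distal: Optional[int] = None


@dataclass
class FamilyConfig:
    families: tuple[FamilySpec, ...]
    taxa_per_family: int = 50
    core_length: int = 240
    # substitution distances (expected fraction of sites replaced)
    core_class_div: float = 0.35
    core_family_div: float = 0.12
    core_taxon_div: float = 0.04
    arm_class_div: float = 0.30
    arm_family_div: float = 0.15
    arm_taxon_div: float = 0.05
    # composition targets: fraction of disorder-promoting residues
    arm_disorder_fraction: float = 0.80
    core_disorder_fraction: float = 0.38
    gc3_noise_sd: float = 2.0  # percentage points around the per-rank target
    # planted class structures (family name -> class label)
    full_classes: dict[str, str] = field(default_factory=dict)
    n_classes: dict[str, str] = field(default_factory=dict)
    c_classes: dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for spec in self.families:
            for f in (self.core_class_div, self.core_family_div, self.core_taxon_div,
                      self.arm_family_div, self.arm_taxon_div):
                if not 0 <= f <= 1:
                    raise ValueError("divergence rates must lie in [0, 1]")
            if spec.n_mean < 0 or spec.c_mean < 0:
                raise ValueError(f"{spec.name}: negative arm length")
        names = [s.name for s in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")


def default_config(taxa_per_family: int = 50, seed: Optional[int] = None) -> FamilyConfig:
    """Seven families shaped like the sirtuin study conditions.

    Arm-length means follow the reported range (N arms 31-170, C arms 0-240;
    family 1 longest, families 4/5 essentially lacking C arms), planted
    stretch counts per family and region follow the reported inventory, every
    family carries an N-arm NES, family 1 additionally the NLS and five CK2
    acceptors adjacent to its three negative N-arm runs, and family 1's C arm
    carries a 7 x 15-residue tandem repeat.  Full-length classes group
    families {1,2,3} | {4} | {5} | {6,7}; N-arm classes {1}|{2}|{3}|{6,7}|{4,5};
    C-arm classes {1,6,7}|{2,3} — the planted discordance between scopes.
    """
    neg, pos = "negative", "positive"
    families = (
        FamilySpec("F1", 170, 15, 240, 20,
                   n_stretches=(neg, neg, neg, pos, pos),
                   c_stretches=(neg, neg, neg),
                   n_motifs=("NES", "NLS"), n_ck2_sites=5,
                   c_repeat=(15, 7), gc3_slope=0.90,
                   n_offset=15, c_offset=90),
        FamilySpec("F2", 120, 12, 100, 10, n_stretches=(neg, neg),
                   n_motifs=("NES",), gc3_slope=0.83, n_offset=28),
        FamilySpec("F3", 100, 10, 30, 5, n_stretches=(pos,),
                   n_motifs=("NES",), gc3_slope=0.30, gc3_intercept=50.0,
                   n_offset=41),
        FamilySpec("F4", 70, 8, 0, 0, n_motifs=("NES",), gc3_slope=0.93,
                   n_offset=56),
        FamilySpec("F5", 70, 8, 0, 0, n_motifs=("NES",), gc3_slope=0.93,
                   n_offset=56),
        FamilySpec("F6", 31, 4, 80, 8, n_stretches=(pos,), c_stretches=(pos,),
                   n_motifs=("NES",), gc3_slope=1.10, n_offset=2),
        FamilySpec("F7", 100, 10, n_stretches=(pos,) * 5, c_stretches=(pos,),
                   c_mean=80, c_sd=8,
                   n_motifs=("NES",), gc3_slope=1.20, n_offset=2,
                   n_proximal_blocks=2, n_distal=35),
    )
    return FamilyConfig(
        families=families,
        taxa_per_family=taxa_per_family,
        full_classes={"F1": "I", "F2": "I", "F3": "I", "F4": "II",
                      "F5": "III", "F6": "IV", "F7": "IV"},
        n_classes={"F1": "N-I", "F2": "N-II", "F3": "N-III", "F6": "N-IV",
                   "F7": "N-IV", "F4": "N-V", "F5": "N-V"},
        c_classes={"F1": "C-I", "F6": "C-I", "F7": "C-I", "F2": "C-II", "F3": "C-II"},
        seed=seed,
    )


def single_family_config(
    taxa: int = 40,
    arm_length: float = 50.0,
    gc3_slope: float = 1.5,
    gc3_intercept: float = 40.0,
    gc3_noise_sd: float = 2.0,
    with_features: bool = False,
    seed: Optional[int] = None,
) -> FamilyConfig:
    """One-family configuration for trend-recovery and composition studies."""
    spec = FamilySpec(
        "F1", arm_length, arm_length * 0.1, arm_length, arm_length * 0.1,
        n_stretches=("negative",) if with_features else (),
        n_motifs=("NES",) if with_features else (),
        gc3_intercept=gc3_intercept, gc3_slope=gc3_slope,
    )
    return FamilyConfig(
        families=(spec,), taxa_per_family=taxa, core_length=120,
        gc3_noise_sd=gc3_noise_sd,
        full_classes={"F1": "I"}, n_classes={"F1": "N-I"}, c_classes={"F1": "C-I"},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground truth

@dataclass(frozen=True)
class TruthFeature:
    protein_id: str
    kind: str  # stretch | motif | repeat | phospho
    name: str  # sign, pattern name, or "repeat"
    start: int  # 1-based inclusive on the final protein
    end: int
    survived: bool = True  # set by corrupt()


@dataclass
class GroundTruth:
    regions: dict[str, RegionAnnotation]
    features: list[TruthFeature]
    gc3_targets: dict[str, float]  # realised per-sequence GC3 target, percent
    full_classes: dict[str, str]
    n_classes: dict[str, str]
    c_classes: dict[str, str]

    def features_of(self, protein_id: str, kind: Optional[str] = None) -> list[TruthFeature]:
        return [
            f for f in self.features
            if f.protein_id == protein_id and (kind is None or f.kind == kind)
        ]


@dataclass
class Bundle:
    config: FamilyConfig
    records: list[SequenceRecord]
    cds: list[CodingRecord]
    alignment: AlignmentBlock
    truth: GroundTruth
    reference_id: str
    ref_core: tuple[int, int]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": out / "proteins.fasta",
            "cds": out / "cds.fasta",
            "alignment": out / "alignment.fasta",
            "metadata": out / "metadata.tsv",
            "truth_features": out / "truth_features.tsv",
            "truth_regions": out / "truth_regions.tsv",
            "config": out / "config_echo.yaml",
        }
        write_fasta(self.records, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        write_alignment(self.alignment, paths["alignment"])
        write_metadata(self.records, paths["metadata"])
        pd.DataFrame([dataclasses.asdict(f) for f in self.truth.features]).to_csv(
            paths["truth_features"], sep="\t", index=False
        )
        rows = []
        for pid, ann in self.truth.regions.items():
            rows.append(
                {
                    "protein_id": pid,
                    "n_start": ann.n_region[0] if ann.n_region else 0,
                    "n_end": ann.n_region[1] if ann.n_region else 0,
                    "core_start": ann.core[0],
                    "core_end": ann.core[1],
                    "c_start": ann.c_region[0] if ann.c_region else 0,
                    "c_end": ann.c_region[1] if ann.c_region else 0,
                }
            )
        pd.DataFrame(rows).to_csv(paths["truth_regions"], sep="\t", index=False)
        echo = json.loads(json.dumps(dataclasses.asdict(self.config)))  # tuples -> lists
        echo["reference_id"] = self.reference_id
        echo["ref_core"] = list(self.ref_core)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# Sequence sampling

def _sample(length: int, dp_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Residue array with an exact count of disorder-promoting residues."""
    n_dp = int(round(dp_fraction * length))
    chars = np.empty(length, dtype="<U1")
    dp_positions = rng.permutation(length)[:n_dp]
    mask = np.zeros(length, dtype=bool)
    mask[dp_positions] = True
    chars[mask] = rng.choice(list(DP_POOL), size=n_dp, p=DP_WEIGHTS)
    chars[~mask] = rng.choice(list(ORDER_POOL), size=length - n_dp, p=ORDER_WEIGHTS)
    return chars


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Class-preserving substitutions: dp residues stay dp, order stay order."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    for pool, weights in ((DP_POOL, DP_WEIGHTS), (ORDER_POOL, ORDER_WEIGHTS)):
        members = np.isin(out, list(pool)) & hit
        k = int(members.sum())
        if k:
            out[members] = rng.choice(list(pool), size=k, p=weights)
    return out


def _fix_dp_fraction(seq: np.ndarray, dp_fraction: float, rng: np.random.Generator) -> None:
    """Swap residues in place until the dp count is exactly round(f * L)."""
    if seq.size == 0:
        return
    want = int(round(dp_fraction * seq.size))
    is_dp = np.isin(seq, list(DP_POOL))
    have = int(is_dp.sum())
    if have > want:
        idx = rng.permutation(np.nonzero(is_dp)[0])[: have - want]
        seq[idx] = rng.choice(list(ORDER_POOL), size=idx.size, p=ORDER_WEIGHTS)
    elif have < want:
        idx = rng.permutation(np.nonzero(~is_dp)[0])[: want - have]
        seq[idx] = rng.choice(list(DP_POOL), size=idx.size, p=DP_WEIGHTS)


# ---------------------------------------------------------------------------
# Feature planting

@dataclass
class _Planted:
    kind: str
    name: str
    start0: int  # 0-based inclusive within the arm
    end0: int
    text: str


def _stretch_text(sign: str, rng: np.random.Generator, span: int = 5) -> str:
    pool = "DE" if sign == "negative" else "KR"
    return "".join(rng.choice(list(pool), size=span))


def _plan_features(spec: FamilySpec, side: str, rng: np.random.Generator) -> list[_Planted]:
    """Feature layout for one arm, packed from the core junction outward.

    Returns features with coordinates relative to the junction: offset 0 is
    the arm residue adjacent to the core; the caller converts to arm-local
    coordinates.  CK2 acceptors ride immediately core-ward of the negative
    stretches they annotate.
    """
    blocks: list[tuple[str, str, str]] = []  # (kind, name, text)
    if side == "N":
        # motifs first: the NES column is the class-shared anchor
        for motif in spec.n_motifs:
            blocks.append(("motif", motif, NES_PLANT if motif == "NES" else NLS_PLANT))
        ck2_left = spec.n_ck2_sites
        neg_seen = 0
        for sign in spec.n_stretches:
            text = _stretch_text(sign, rng)
            # the CK2 block precedes its stretch so the T acceptors (at the
            # block's junction-proximal end) fall within the proximity window
            if sign == "negative" and ck2_left > 0:
                neg_seen += 1
                take = CK2_DOUBLE if ck2_left >= 2 and neg_seen <= 2 else CK2_SINGLE
                n_sites = 2 if take == CK2_DOUBLE else 1
                blocks.append(("ck2", "CK2", take))
                ck2_left -= n_sites
            blocks.append(("stretch", sign, text))
        base, distal, proximal = spec.n_offset, spec.n_distal, spec.n_proximal_blocks
    else:
        for sign in spec.c_stretches:
            blocks.append(("stretch", sign, _stretch_text(sign, rng)))
        if spec.c_repeat is not None:
            unit_len, copies = spec.c_repeat
            if unit_len != len(REPEAT_UNIT):
                raise ValueError(f"unit length must be {len(REPEAT_UNIT)}")
            blocks.append(("repeat", "repeat", REPEAT_UNIT * copies))
        base, distal, proximal = spec.c_offset, None, None
    planted = []
    offset = base
    for k, (kind, name, text) in enumerate(blocks):
        if proximal is not None and distal is not None and k == proximal:
            offset = max(offset, distal)
        planted.append(_Planted(kind, name, offset, offset + len(text) - 1, text))
        offset += len(text) + _FLANK
    return planted


def _required_length(planted: Sequence[_Planted]) -> int:
    return (planted[-1].end0 + 1 + _FLANK) if planted else 0


def _apply_features(arm: np.ndarray, planted: Sequence[_Planted], side: str) -> list[tuple[_Planted, int]]:
    """Write features into the arm; return (feature, 0-based arm start) pairs.

    N-side offsets count from the junction (arm end) leftward, C-side from
    the junction (arm start) rightward.
    """
    out = []
    L = arm.size
    for p in planted:
        if side == "N":
            start = L - 1 - p.end0
        else:
            start = p.start0
        arm[start : start + len(p.text)] = list(p.text)
        # neutral flanks so detected extents match planted extents exactly
        for flank_pos in range(start - _FLANK, start):
            if 0 <= flank_pos < L:
                arm[flank_pos] = _NEUTRAL[flank_pos % len(_NEUTRAL)]
        for flank_pos in range(start + len(p.text), start + len(p.text) + _FLANK):
            if 0 <= flank_pos < L:
                arm[flank_pos] = _NEUTRAL[flank_pos % len(_NEUTRAL)]
        out.append((p, start))
    return out


# ---------------------------------------------------------------------------
# Sanitisation against the detectors

def _truth_spans(features: Sequence[TruthFeature]) -> dict[str, set]:
    spans: dict[str, set] = {"stretch": set(), "NES": set(), "NLS": set(), "repeat": set()}
    for f in features:
        if f.kind == "stretch":
            spans["stretch"].add((f.start, f.end, f.name))
        elif f.kind == "motif":
            spans.setdefault(f.name, set()).add((f.start, f.end))
        elif f.kind == "repeat":
            spans["repeat"].add((f.start, f.end))
    return spans


def _sanitize(seq: np.ndarray, features: Sequence[TruthFeature],
              rng: np.random.Generator, max_rounds: int = 120) -> None:
    """Mutate background until every detector hit is a planted feature."""
    spans = _truth_spans(features)
    protected = np.zeros(seq.size, dtype=bool)
    for f in features:
        protected[f.start - 1 : f.end] = True

    for _ in range(max_rounds):
        text = "".join(seq)
        offenders: list[tuple[int, int]] = []
        for st in _stretches.find_stretches(text, mode="lenient"):
            if (st.start, st.end, st.sign) not in spans["stretch"]:
                offenders.append((st.start, st.end))
        for name in ("NES", "NLS"):
            for hit in _motifs.scan_pattern(text, _motifs.BUILTIN_PATTERNS[name]):
                if (hit.start, hit.end) not in spans[name]:
                    offenders.append((hit.start, hit.end))
        for rep in _motifs.find_tandem_repeats(text):
            if (rep.start, rep.end) not in spans["repeat"]:
                offenders.append((rep.start, rep.end))
        if not offenders:
            return
        for start, end in offenders:
            mutable = [i for i in range(start - 1, end) if not protected[i]]
            if not mutable:
                raise RuntimeError("spurious hit entirely inside planted features")
            pos = mutable[rng.integers(len(mutable))] if len(mutable) > 1 else mutable[0]
            options = [c for c in _NEUTRAL if c != seq[pos]]
            seq[pos] = options[rng.integers(len(options))]
    raise RuntimeError("sanitisation did not converge")


# ---------------------------------------------------------------------------
# Coding sequences

_CODON_PREFIX = {
    "A": ("GC", "CGTA"), "R": ("CG", "CGTA"), "N": ("AA", "CT"), "D": ("GA", "CT"),
    "C": ("TG", "CT"), "Q": ("CA", "GA"), "E": ("GA", "GA"), "G": ("GG", "CGTA"),
    "H": ("CA", "CT"), "I": ("AT", "CT"), "L": ("CT", "CGTA"), "K": ("AA", "GA"),
    "M": ("AT", "G"), "F": ("TT", "CT"), "P": ("CC", "CGTA"), "S": ("TC", "CGTA"),
    "T": ("AC", "CGTA"), "W": ("TG", "G"), "V": ("GT", "CGTA"), "Y": ("TA", "CT"),
}
# third-base choice per residue: (GC-rich option, AT option); None = forced
_THIRD = {
    aa: (None if len(opts) == 1 else (opts[0], opts[-1] if opts[-1] in "TA" else "A"))
    for aa, (prefix, opts) in _CODON_PREFIX.items()
}


class InfeasibleGCError(ValueError):
    pass


def _build_cds(protein: str, gc3_target: float, rng: np.random.Generator) -> str:
    """Codons with exact-count third-base selection hitting the GC3 target.

    ``gc3_target`` is a fraction.  The feasible interval is bounded below by
    the Met/Trp codons whose third base is forced to G.
    """
    n = len(protein)
    forced_gc = sum(1 for aa in protein if _THIRD[aa] is None)
    free_idx = [i for i, aa in enumerate(protein) if _THIRD[aa] is not None]
    lo = forced_gc / n
    if not (lo - 1e-9 <= gc3_target <= 1 + 1e-9):
        raise InfeasibleGCError(
            f"GC3 target {gc3_target:.3f} outside feasible interval "
            f"[{lo:.3f}, 1.000] for this amino-acid composition"
        )
    want_gc = int(round(gc3_target * n)) - forced_gc
    want_gc = min(max(want_gc, 0), len(free_idx))
    gc_positions = set(
        np.asarray(free_idx)[rng.permutation(len(free_idx))[:want_gc]].tolist()
    )
    codons = []
    for i, aa in enumerate(protein):
        prefix, opts = _CODON_PREFIX[aa]
        if _THIRD[aa] is None:
            codons.append(prefix + opts)
        else:
            gc_opt, at_opt = _THIRD[aa]
            codons.append(prefix + (gc_opt if i in gc_positions else at_opt))
    return "".join(codons)


# ---------------------------------------------------------------------------
# Generation

def _block_alignment(records, arms, fam_by_id, n_classes, c_classes) -> AlignmentBlock:
    """Assemble rows as [N-class blocks][core][C-class blocks].

    Within its block an N arm is right-aligned against the core junction and
    a C arm left-aligned; a row is all-gap in every block of a class other
    than its own.
    """
    def widths(class_map, side_idx):
        w = {}
        for rec in records:
            cls = class_map.get(fam_by_id[rec.id])
            if cls is None:
                continue
            w[cls] = max(w.get(cls, 0), len(arms[rec.id][side_idx]))
        return dict(sorted(w.items()))

    n_widths = widths(n_classes, 0)
    c_widths = widths(c_classes, 1)
    rows = []
    for rec in records:
        n_arm, c_arm = arms[rec.id]
        core_part = rec.residues[len(n_arm): len(rec.residues) - len(c_arm)
                                 if c_arm else len(rec.residues)]
        n_cls = n_classes.get(fam_by_id[rec.id])
        c_cls = c_classes.get(fam_by_id[rec.id])
        n_part = "".join(
            ("-" * (w - len(n_arm)) + n_arm) if cls == n_cls and n_arm else "-" * w
            for cls, w in n_widths.items()
        )
        c_part = "".join(
            (c_arm + "-" * (w - len(c_arm))) if cls == c_cls and c_arm else "-" * w
            for cls, w in c_widths.items()
        )
        rows.append((rec.id, n_part + core_part + c_part))
    return AlignmentBlock(rows=rows)


def generate_family(config: FamilyConfig, seed: Optional[int] = None) -> Bundle:
    """Generate the full bundle: proteins, CDS, alignment, metadata, truth.

    Deterministic given the seed (byte-identical files on rerun).  Raises
    :class:`InfeasibleGCError` when a configured GC3 trend leaves the range
    achievable by synonymous codon choice.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    core_len = config.core_length

    # --- ancestral cores per full-length class
    root_core = _sample(core_len, config.core_disorder_fraction, rng)
    class_cores = {
        cls: _mutate(root_core, config.core_class_div, rng)
        for cls in sorted(set(config.full_classes.values()))
    }
    family_cores = {
        spec.name: _mutate(class_cores[config.full_classes[spec.name]],
                           config.core_family_div, rng)
        for spec in config.families
    }

    # --- ancestral arms per arm-class, evolved from one root arm per side so
    # cross-class arm divergence stays moderate and full-length distances are
    # dominated by the core signal
    def arm_class_ancestors(class_map: dict[str, str], side: str) -> dict[str, np.ndarray]:
        def reach(s: FamilySpec) -> float:
            return s.n_mean + 5 * s.n_sd if side == "N" else s.c_mean + 5 * s.c_sd

        named = [s for s in config.families if s.name in class_map]
        if not named:
            return {}
        root_len = int(np.ceil(max(reach(s) for s in named))) + 1
        root_arm = _sample(root_len, config.arm_disorder_fraction, rng)
        out = {}
        for cls in sorted(set(class_map.values())):
            members = [s for s in named if class_map[s.name] == cls]
            longest = int(np.ceil(max(reach(s) for s in members))) + 1
            anc = _mutate(root_arm, config.arm_class_div, rng)
            # keep the junction-proximal end: suffix for N arms, prefix for C
            out[cls] = anc[root_len - longest:] if side == "N" else anc[:longest]
        return out

    n_class_arms = arm_class_ancestors(config.n_classes, "N")
    c_class_arms = arm_class_ancestors(config.c_classes, "C")
    family_arms = {}
    for spec in config.families:
        n_anc = _mutate(n_class_arms[config.n_classes[spec.name]],
                        config.arm_family_div, rng)
        c_cls = config.c_classes.get(spec.name)
        c_anc = (_mutate(c_class_arms[c_cls], config.arm_family_div, rng)
                 if c_cls is not None and spec.c_mean > 0 else np.empty(0, dtype="<U1"))
        family_arms[spec.name] = (n_anc, c_anc)

    # --- per-family feature plans (identical layout for every member)
    plans = {
        spec.name: (_plan_features(spec, "N", rng), _plan_features(spec, "C", rng))
        for spec in config.families
    }

    records: list[SequenceRecord] = []
    cds_records: list[CodingRecord] = []
    regions: dict[str, RegionAnnotation] = {}
    features: list[TruthFeature] = []
    gc3_targets: dict[str, float] = {}
    aligned_arms: dict[str, tuple[str, str]] = {}

    for spec in config.families:
        n_anc, c_anc = family_arms[spec.name]
        n_plan, c_plan = plans[spec.name]
        n_min = max(_required_length(n_plan), 0)
        c_min = max(_required_length(c_plan), 0)
        for t in range(1, config.taxa_per_family + 1):
            pid = f"{spec.name}_t{t:02d}"
            rank = t
            # arm lengths
            Ln = 0
            if spec.n_mean > 0 or n_min:
                Ln = int(round(rng.normal(spec.n_mean, spec.n_sd)))
                Ln = min(max(Ln, n_min, 0), n_anc.size)
            Lc = 0
            if spec.c_mean > 0:
                Lc = int(round(rng.normal(spec.c_mean, spec.c_sd)))
                Lc = min(max(Lc, c_min, 0), c_anc.size)
            n_arm = _mutate(n_anc, config.arm_taxon_div, rng)[n_anc.size - Ln:]
            c_arm = _mutate(c_anc, config.arm_taxon_div, rng)[:Lc]
            _fix_dp_fraction(n_arm, config.arm_disorder_fraction, rng)
            _fix_dp_fraction(c_arm, config.arm_disorder_fraction, rng)
            core = _mutate(family_cores[spec.name], config.core_taxon_div, rng)

            n_placed = _apply_features(n_arm, n_plan, "N") if Ln else []
            c_placed = _apply_features(c_arm, c_plan, "C") if Lc else []

            seq = np.concatenate([n_arm, core, c_arm])
            ann = RegionAnnotation(
                pid, seq.size,
                core=(Ln + 1, Ln + core_len),
                n_region=(1, Ln) if Ln else None,
                c_region=(Ln + core_len + 1, seq.size) if Lc else None,
            )

            seq_features: list[TruthFeature] = []
            for placed, offset in ((n_placed, 0), (c_placed, Ln + core_len)):
                for p, arm_start in placed:
                    start = offset + arm_start + 1
                    end = start + len(p.text) - 1
                    if p.kind == "stretch":
                        seq_features.append(TruthFeature(pid, "stretch", p.name, start, end))
                    elif p.kind == "motif":
                        seq_features.append(TruthFeature(pid, "motif", p.name, start, end))
                        if p.name == "NLS":  # RKKRKD embeds a positive run
                            seq_features.append(
                                TruthFeature(pid, "stretch", "positive", start, start + 4)
                            )
                    elif p.kind == "ck2":
                        seq_features.append(TruthFeature(pid, "motif", "CK2", start, end))
                        acceptors = (0, 1) if p.text == CK2_DOUBLE else (0,)
                        for a in acceptors:
                            seq_features.append(
                                TruthFeature(pid, "phospho", "CK2", start + a, start + a)
                            )
                    elif p.kind == "repeat":
                        seq_features.append(TruthFeature(pid, "repeat", "repeat", start, end))

            _sanitize(seq, seq_features, rng)

            protein = "".join(seq)
            gc3 = spec.gc3_intercept + spec.gc3_slope * rank
            if config.gc3_noise_sd > 0:
                gc3 += rng.normal(0.0, config.gc3_noise_sd)
            # the configured line itself must be feasible; noise is clipped
            forced_lo = 100 * sum(1 for aa in protein if _THIRD[aa] is None) / len(protein)
            line_val = spec.gc3_intercept + spec.gc3_slope * rank
            if not (forced_lo <= line_val <= 100):
                raise InfeasibleGCError(
                    f"{spec.name}: configured GC3 {line_val:.1f}% at rank {rank} "
                    f"outside feasible interval [{forced_lo:.1f}%, 100%]"
                )
            gc3 = min(max(gc3, forced_lo), 100.0)
            cds = _build_cds(protein, gc3 / 100.0, rng)

            records.append(
                SequenceRecord(pid, protein, organism=f"org{rank:02d}",
                               family=spec.name, rank=rank)
            )
            cds_records.append(CodingRecord(pid, cds))
            regions[pid] = ann
            features.extend(seq_features)
            gc3_targets[pid] = gc3
            aligned_arms[pid] = (protein[:Ln], protein[len(protein) - Lc:] if Lc else "")

    # --- alignment: one column block per arm class around the shared core.
    # Arms are alignable only within their class (they have separate
    # histories), so each row carries residues in its own class's block and
    # gaps across every other: cross-class arm pairs share no columns and
    # full-length distances stay core-driven.
    fam_by_id = {rec.id: rec.family for rec in records}
    alignment = _block_alignment(
        records, aligned_arms, fam_by_id, config.n_classes, config.c_classes
    )
    alignment.validate_against(records)

    # reference: the row with the widest arms (ties: first)
    reference_id = max(records, key=lambda r: len(r.residues)).id
    ref_ann = regions[reference_id]
    ref_core = ref_ann.core

    truth = GroundTruth(
        regions=regions, features=features, gc3_targets=gc3_targets,
        full_classes=dict(config.full_classes),
        n_classes=dict(config.n_classes),
        c_classes=dict(config.c_classes),
    )
    return Bundle(config, records, cds_records, alignment, truth,
                  reference_id, ref_core)


# ---------------------------------------------------------------------------
# Robustness corruption

def corrupt(bundle: Bundle, rate: float, seed: int = 0) -> Bundle:
    """Substitution noise on the arms; records post-noise feature survival.

    ``rate`` is the per-residue substitution probability on arm positions
    (cores untouched).  A feature survives when its detector still reports a
    hit at the original coordinates.  Rate 0 returns an identical bundle.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0:
        return bundle
    rng = np.random.default_rng(seed)
    pool = list(DP_POOL + ORDER_POOL)
    weights = np.concatenate([
        DP_WEIGHTS * bundle.config.arm_disorder_fraction,
        ORDER_WEIGHTS * (1 - bundle.config.arm_disorder_fraction),
    ])
    weights = weights / weights.sum()

    new_records = []
    new_cds = []
    new_arms = {}
    for rec, cds in zip(bundle.records, bundle.cds):
        ann = bundle.truth.regions[rec.id]
        seq = np.array(list(rec.residues), dtype="<U1")
        arm_mask = np.zeros(seq.size, dtype=bool)
        if ann.n_region:
            arm_mask[ann.n_region[0] - 1 : ann.n_region[1]] = True
        if ann.c_region:
            arm_mask[ann.c_region[0] - 1 : ann.c_region[1]] = True
        hit = (rng.random(seq.size) < rate) & arm_mask
        k = int(hit.sum())
        if k:
            seq[hit] = rng.choice(pool, size=k, p=weights)
        protein = "".join(seq)
        new_records.append(dataclasses.replace(rec, residues=protein))
        new_cds.append(CodingRecord(rec.id, _build_cds(
            protein, bundle.truth.gc3_targets[rec.id] / 100.0, rng)))
        n_len = ann.region_length("N")
        c_len = ann.region_length("C")
        new_arms[rec.id] = (protein[:n_len], protein[len(protein) - c_len:] if c_len else "")

    # survival per feature
    by_pid = {r.id: r.residues for r in new_records}
    survived_features = []
    detector_cache: dict[str, dict] = {}
    for f in bundle.truth.features:
        seq = by_pid[f.protein_id]
        if f.protein_id not in detector_cache:
            detector_cache[f.protein_id] = {
                "stretch": {(s.start, s.end, s.sign)
                            for s in _stretches.find_stretches(seq, "lenient")},
                "NES": {(h.start, h.end)
                        for h in _motifs.scan_pattern(seq, _motifs.NES)},
                "NLS": {(h.start, h.end)
                        for h in _motifs.scan_pattern(seq, _motifs.NLS)},
                "CK2": {(h.start, h.end)
                        for h in _motifs.scan_pattern(seq, _motifs.CK2)},
                "repeat": {(r.start, r.end)
                           for r in _motifs.find_tandem_repeats(seq)},
            }
        cache = detector_cache[f.protein_id]
        if f.kind == "stretch":
            ok = (f.start, f.end, f.name) in cache["stretch"]
        elif f.kind == "motif":
            ok = (f.start, f.end) in cache[f.name]
        elif f.kind == "phospho":
            ok = by_pid[f.protein_id][f.start - 1] in "STY"
        else:
            ok = (f.start, f.end) in cache["repeat"]
        survived_features.append(dataclasses.replace(f, survived=ok))

    fam_by_id = {rec.id: rec.family for rec in new_records}
    alignment = _block_alignment(
        new_records, new_arms, fam_by_id,
        bundle.config.n_classes, bundle.config.c_classes,
    )
    truth = GroundTruth(
        regions=bundle.truth.regions, features=survived_features,
        gc3_targets=bundle.truth.gc3_targets,
        full_classes=bundle.truth.full_classes,
        n_classes=bundle.truth.n_classes,
        c_classes=bundle.truth.c_classes,
    )
    return Bundle(bundle.config, new_records, new_cds, alignment, truth,
                  bundle.reference_id, bundle.ref_core)
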