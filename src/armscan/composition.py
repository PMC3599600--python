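"""Per-region composition, charged fractions, and disorder calling.

Charged residues are exactly {K, R, D, E}; histidine is treated as uncharged
throughout the package.  'X' wildcards are excluded from every denominator so
all fractions stay well-defined.  Disorder can come from external predictor
tracks (combined by consensus) or from a built-in windowed propensity proxy
over the packaged TOP-IDP composition scale.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, AnnotationTrack, SequenceRecord
from .segmentation import RegionAnnotation

CHARGED = frozenset("KRDE")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: disorder-promoting residues: positive TOP-IDP propensity above the T/A level
DISORDER_PROMOTING = frozenset("TAGRDHQSKEP")


def load_scale(name: str = "top_idp") -> dict[str, float]:
    """Load a packaged per-residue propensity scale (TSV: residue, propensity)."""
    ref = importlib.resources.files("armscan.data") / f"{name}.tsv"
    df = pd.read_csv(ref, sep="\t", comment="#")
    return dict(zip(df["residue"], df["propensity"].astype(float)))


def load_reference_freqs() -> pd.DataFrame:
    """Packaged synthetic stand-in disordered/ordered frequency table."""
    ref = importlib.resources.files("armscan.data") / "synthetic_disorder_reference_freqs.tsv"
    return pd.read_csv(ref, sep="\t", comment="#")


@dataclass
class CompositionProfile:
    protein_id: str
    region: str  # N | core | C | full
    counts: dict[str, int]
    fraction_charged: Optional[float]  # None when the region is empty
    fraction_cys: Optional[float]
    length: int  # region length including any X residues

    @property
    def missing(self) -> bool:
        return self.fraction_charged is None


@dataclass
class DisorderCall:
    """Binary per-residue disorder vector plus its provenance."""

    protein_id: str
    calls: np.ndarray  # bool, length = protein length
    source: str  # "proxy" or a consensus-mode label

    @property
    def fraction_disordered(self) -> float:
        return float(self.calls.mean())

    def region_fraction(self, annotation: RegionAnnotation, region: str) -> Optional[float]:
        span = annotation.region_span(region)
        if span is None:
            return None
        return float(self.calls[span[0] - 1 : span[1]].mean())


def _region_residues(record: SequenceRecord, annotation: Optional[RegionAnnotation],
                     region: str) -> str:
    if region == "full":
        return record.residues
    if annotation is None:
        raise ValueError("a RegionAnnotation is required for region != full")
    span = annotation.region_span(region)
    return "" if span is None else record.residues[span[0] - 1 : span[1]]


def composition_profile(
    record: SequenceRecord,
    annotation: Optional[RegionAnnotation] = None,
    region: str = "full",
) -> CompositionProfile:
    """Residue counts and charged/Cys fractions for one region.

    An empty region yields zero counts and *missing* (None) fractions, never
    0.0, so family averages run over non-empty regions only.
    """
    residues = _region_residues(record, annotation, region)
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for ch in residues:
        if ch != "X":
            counts[ch] += 1
    denom = sum(counts.values())
    if denom == 0:
        return CompositionProfile(record.id, region, counts, None, None, len(residues))
    charged = sum(counts[aa] for aa in CHARGED)
    return CompositionProfile(
        record.id,
        region,
        counts,
        fraction_charged=charged / denom,
        fraction_cys=counts["C"] / denom,
        length=len(residues),
    )


def disorder_enrichment(
    profile: CompositionProfile,
    reference_freqs: pd.DataFrame,
    against: Literal["disordered", "ordered"] = "disordered",
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """Per-residue log2 enrichment of observed composition vs a reference class.

    Observed fractions are smoothed with ``pseudocount`` additive counts so
    zero-count residues stay finite.  The reference table must cover all 20
    residues in both the disordered and ordered columns.
    """
    required = {"residue", "disordered", "ordered"}
    if required - set(reference_freqs.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    ref = dict(zip(reference_freqs["residue"], reference_freqs[against].astype(float)))
    missing = set(AMINO_ACIDS) - set(ref)
    if missing:
        raise ValueError(f"reference table missing residues: {sorted(missing)}")
    total = sum(profile.counts.values())
    denom = total + pseudocount * 20
    out = {}
    for aa in AMINO_ACIDS:
        observed = (profile.counts[aa] + pseudocount) / denom
        out[aa] = math.log2(observed / ref[aa])
    return out


def disorder_proxy(
    record: SequenceRecord,
    scale: Optional[Mapping[str, float]] = None,
    window: int = 21,
    threshold: float = 0.0,
) -> DisorderCall:
    """Windowed-propensity disorder caller (proxy for external predictors).

    Residue i is called disordered when the mean propensity over an odd
    window centred at i (truncated at the termini) exceeds ``threshold``.
    'X' residues contribute a neutral propensity of 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if scale is None:
        scale = load_scale()
    values = np.array([scale.get(ch, 0.0) for ch in record.residues], dtype=float)
    half = window // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    means = (csum[ends] - csum[starts]) / (ends - starts)
    return DisorderCall(record.id, means > threshold, source="proxy")


def consensus_disorder(
    tracks: Sequence[AnnotationTrack],
    mode: Literal["intersection", "union"] = "intersection",
) -> DisorderCall:
    """Combine >=2 external disorder tracks into one call vector."""
    if len(tracks) < 2:
        raise ValueError("consensus needs at least two tracks")
    pid = tracks[0].protein_id
    vectors = []
    for t in tracks:
        if t.kind != "disorder" or t.disorder is None:
            raise ValueError(f"{t.protein_id}: not a disorder track")
        if t.protein_id != pid:
            raise ValueError("tracks refer to different proteins")
        vectors.append(np.frombuffer(t.disorder.encode(), dtype=np.uint8) == ord("1"))
    lengths = {v.size for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"{pid}: track length mismatch: {sorted(lengths)}")
    stacked = np.vstack(vectors)
    calls = stacked.all(axis=0) if mode == "intersection" else stacked.any(axis=0)
    return DisorderCall(pid, calls, source=f"tracks-{mode}")


def composition_table(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, RegionAnnotation],
) -> pd.DataFrame:
    """One row per protein x region with charged/Cys percentages."""
    rows = []
    for rec in records:
        ann = annotations.get(rec.id)
        if ann is None or ann.status == "unsegmentable":
            continue
        for region in ("N", "core", "C", "full"):
            prof = composition_profile(rec, ann, region)
            rows.append(
                {
                    "protein_id": rec.id,
                    "family": rec.family,
                    "region": region,
                    "length": prof.length,
                    "pct_charged": None if prof.missing else 100 * prof.fraction_charged,
                    "pct_cys": None if prof.missing else 100 * prof.fraction_cys,
                }
            )
    return pd.DataFrame(rows)


def disorder_table(
    calls: Sequence[DisorderCall],
    annotations: Mapping[str, RegionAnnotation],
    families: Mapping[str, str],
) -> pd.DataFrame:
    """Per protein x region percentage of residues called disordered."""
    rows = []
    for call in calls:
        ann = annotations.get(call.protein_id)
        if ann is None or ann.status == "unsegmentable":
            continue
        for region in ("N", "core", "C", "full"):
            frac = (
                call.fraction_disordered
                if region == "full"
                else call.region_fraction(ann, region)
            )
            rows.append(
                {
                    "protein_id": call.protein_id,
                    "family": families.get(call.protein_id),
                    "region": region,
                    "pct_disordered": None if frac is None else 100 * frac,
                    "source": call.source,
                }
            )
    return pd.DataFrame(rows)
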