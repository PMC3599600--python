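"""GC metrics on coding sequences, isochore classes, and evolutionary trends.

GC is computed on the coding strand only, overall and split by structural
region (residue i owns codon nucleotides 3i-2..3i) and by codon position.
'N' bases are excluded from numerator and denominator.  Trends are ordinary
least-squares lines of GC percent against phylogenetic rank; families are
compared by their slopes ("angular coefficients").  Isochore classes follow
the human-genome compositional families: L (GC-poor, the L1/L2 range),
H1 (moderately GC-rich, 41-46%), H (very GC-rich, 46% and above).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import CodingRecord, SequenceRecord
from .segmentation import RegionAnnotation

REGION_PARTS = ("full", "N", "core", "C")


@dataclass
class GCProfile:
    protein_id: str
    gc_full: float
    gc_n: Optional[float]  # None when the region is empty
    gc_core: Optional[float]
    gc_c: Optional[float]
    gc1: float
    gc2: float
    gc3: float


@dataclass
class TrendFit:
    """OLS line of GC% over rank for one family and sequence part."""

    family: str
    part: str  # full | N | core | C
    slope: float
    intercept: float
    n: int
    slope_se: float
    residual_se: float


@dataclass(frozen=True)
class IsochoreClass:
    label: Literal["L", "H1", "H"]
    gc_value: float

    @property
    def description(self) -> str:
        return {
            "L": "GC-poor (L1/L2)",
            "H1": "moderately GC-rich",
            "H": "very GC-rich (H2/H3)",
        }[self.label]


def _gc_fraction(bases: str) -> Optional[float]:
    gc = sum(1 for b in bases if b in "GC")
    atgc = sum(1 for b in bases if b in "ACGT")
    return None if atgc == 0 else gc / atgc


def gc_profile(
    pair: tuple[SequenceRecord, CodingRecord],
    annotation: Optional[RegionAnnotation] = None,
) -> GCProfile:
    """Overall, per-region, and per-codon-position GC of one coding sequence."""
    protein, cds = pair
    nt = cds.nucleotides
    if len(nt) not in (3 * len(protein), 3 * len(protein) + 3):  # optional stop codon
        raise ValueError(
            f"{protein.id}: CDS length {len(nt)} does not frame {len(protein)} residues"
        )
    coding = nt[: 3 * len(protein)]

    def region_gc(region: str) -> Optional[float]:
        if annotation is None:
            return None
        span = annotation.region_span(region)
        if span is None:
            return None
        return _gc_fraction(coding[3 * (span[0] - 1) : 3 * span[1]])

    return GCProfile(
        protein_id=protein.id,
        gc_full=_gc_fraction(coding),
        gc_n=region_gc("N"),
        gc_core=region_gc("core"),
        gc_c=region_gc("C"),
        gc1=_gc_fraction(coding[0::3]),
        gc2=_gc_fraction(coding[1::3]),
        gc3=_gc_fraction(coding[2::3]),
    )


def gc_table(
    pairs: Sequence[tuple[SequenceRecord, CodingRecord]],
    annotations: Optional[dict[str, RegionAnnotation]] = None,
) -> pd.DataFrame:
    """One row per gene with all GC percentages (printed scale: percent)."""
    rows = []
    for protein, cds in pairs:
        ann = annotations.get(protein.id) if annotations else None
        if ann is not None and ann.status == "unsegmentable":
            ann = None
        prof = gc_profile((protein, cds), ann)

        def pct(x):
            return None if x is None else 100 * x

        rows.append(
            {
                "protein_id": protein.id,
                "family": protein.family,
                "rank": protein.rank,
                "gc_full": pct(prof.gc_full),
                "gc_n": pct(prof.gc_n),
                "gc_core": pct(prof.gc_core),
                "gc_c": pct(prof.gc_c),
                "gc1": pct(prof.gc1),
                "gc2": pct(prof.gc2),
                "gc3": pct(prof.gc3),
            }
        )
    return pd.DataFrame(rows)


def fit_trend(
    points: Sequence[tuple[float, float]],
    family: str = "",
    part: str = "full",
) -> TrendFit:
    """OLS of GC% (y) on phylogenetic rank (x); slope is the angular coefficient."""
    if len(points) < 2:
        raise ValueError("trend fit needs at least two points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("degenerate x: all ranks equal")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    dof = max(len(x) - 2, 1)
    residual_se = math.sqrt(float(np.sum((y - fitted) ** 2)) / dof)
    return TrendFit(
        family=family,
        part=part,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
        slope_se=float(res.stderr),
        residual_se=residual_se,
    )


def family_trends(
    gc: pd.DataFrame,
    aggregation: Literal["sequence", "organism-mean"] = "sequence",
    organisms: Optional[dict[str, str]] = None,
) -> list[TrendFit]:
    """Per family x part trend fits from a gc_table frame.

    ``organism-mean`` first averages sequences sharing a rank (one point per
    rank), the alternative reading of plotting one point per organism.
    """
    part_col = {"full": "gc_full", "N": "gc_n", "core": "gc_core", "C": "gc_c"}
    fits = []
    for family, sub in gc.groupby("family", sort=True):
        for part, col in part_col.items():
            pts = sub[["rank", col]].dropna()
            if aggregation == "organism-mean":
                pts = pts.groupby("rank", as_index=False)[col].mean()
            if len(pts) < 2 or pts["rank"].nunique() < 2:
                continue
            fits.append(
                fit_trend(list(zip(pts["rank"], pts[col])), family=family, part=part)
            )
    return fits


def compare_slopes(fits: Sequence[TrendFit]) -> pd.DataFrame:
    """Families ordered by angular coefficient with pairwise slope z-scores.

    z = (a1 - a2) / sqrt(se1^2 + se2^2) for each ordered pair, descending
    slope order.
    """
    if len(fits) < 2:
        raise ValueError("slope comparison needs at least two fits")
    ordered = sorted(fits, key=lambda f: (-f.slope, f.family, f.part))
    rows = []
    for a, b in itertools.combinations(ordered, 2):
        denom = math.sqrt(a.slope_se**2 + b.slope_se**2)
        z = 0.0 if a.slope == b.slope else (a.slope - b.slope) / denom
        rows.append(
            {
                "family_a": a.family, "part_a": a.part, "slope_a": a.slope,
                "family_b": b.family, "part_b": b.part, "slope_b": b.slope,
                "z": z,
            }
        )
    return pd.DataFrame(rows)


def trends_table(fits: Sequence[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "part": [f.part for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "residual_se": [f.residual_se for f in fits],
            "n": [f.n for f in fits],
        }
    )


def classify_isochore(gc_percent: float) -> IsochoreClass:
    """Total, deterministic isochore classification with half-open boundaries.

    [0, 41) -> L (GC-poor); [41, 46) -> H1; [46, 100] -> H (very GC-rich).
    """
    if not 0 <= gc_percent <= 100:
        raise ValueError(f"GC percentage out of range: {gc_percent}")
    if gc_percent < 41:
        label = "L"
    elif gc_percent < 46:
        label = "H1"
    else:
        label = "H"
    return IsochoreClass(label, gc_percent)


@dataclass(frozen=True)
class ConcordanceRecord:
    gene_gc: float
    band_gc: float
    gene_class: str
    band_class: str
    concordant: bool


def gene_vs_band(gene_gc: float, band_gc: float) -> ConcordanceRecord:
    """Concordance of a gene's isochore class with its chromosomal band's."""
    g = classify_isochore(gene_gc)
    b = classify_isochore(band_gc)
    return ConcordanceRecord(gene_gc, band_gc, g.label, b.label, g.label == b.label)
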