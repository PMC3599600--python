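"""Tripartite partition of family members: N-arm, catalytic core, C-arm.

The core interval is fixed once, on one reference sequence, and projected
through the multiple alignment onto every other row: the reference core maps
to an alignment column span, and each row's core is the set of its ungapped
positions covered by those columns.  Arms are whatever flanks the core.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .seqio import AlignmentBlock

logger = logging.getLogger(__name__)

REGIONS = ("N", "core", "C")


@dataclass
class RegionAnnotation:
    """1-based inclusive tripartite partition of one ungapped sequence.

    ``status`` is "ok", "partial" (projected core shorter than the configured
    fraction of the reference core; excluded from per-region statistics) or
    "unsegmentable" (row all-gap across the core columns; excluded downstream).
    """

    protein_id: str
    length: int
    core: Optional[tuple[int, int]]
    n_region: Optional[tuple[int, int]] = None
    c_region: Optional[tuple[int, int]] = None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "unsegmentable":
            return
        if self.core is None or self.core[0] > self.core[1]:
            raise ValueError(f"{self.protein_id}: empty core")
        n_len = self.region_length("N")
        c_len = self.region_length("C")
        core_len = self.region_length("core")
        if n_len + core_len + c_len != self.length:
            raise ValueError(f"{self.protein_id}: regions do not cover the sequence")
        if self.n_region is not None and self.n_region[1] + 1 != self.core[0]:
            raise ValueError(f"{self.protein_id}: N-arm and core not contiguous")
        if self.c_region is not None and self.core[1] + 1 != self.c_region[0]:
            raise ValueError(f"{self.protein_id}: core and C-arm not contiguous")

    def region_span(self, region: str) -> Optional[tuple[int, int]]:
        if region == "N":
            return self.n_region
        if region == "core":
            return self.core
        if region == "C":
            return self.c_region
        if region == "full":
            return (1, self.length)
        raise ValueError(f"unknown region {region!r}")

    def region_length(self, region: str) -> int:
        span = self.region_span(region)
        return 0 if span is None else span[1] - span[0] + 1

    def region_of(self, position: int) -> str:
        """Region label holding a 1-based position."""
        for region in REGIONS:
            span = self.region_span(region)
            if span is not None and span[0] <= position <= span[1]:
                return region
        raise ValueError(f"{self.protein_id}: position {position} out of range")


def _column_map(gapped: str) -> list[int]:
    """Alignment column (0-based) of each ungapped position (0-based)."""
    return [col for col, ch in enumerate(gapped) if ch != "-"]


def project_core(
    alignment: AlignmentBlock,
    reference_id: str,
    ref_core: tuple[int, int],
    partial_fraction: float = 0.5,
) -> list[RegionAnnotation]:
    """Project reference core boundaries through the alignment onto every row.

    When a core boundary column is gapped in a target row, the core start
    snaps to the next ungapped target position inside the span and the core
    end to the previous one (core maximal-inside, arms maximal-outside).
    Rows all-gap across the core columns are flagged unsegmentable; rows whose
    projected core is shorter than ``partial_fraction`` of the reference core
    are flagged partial.
    """
    if reference_id not in alignment.ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref_row = alignment.row(reference_id)
    ref_cols = _column_map(ref_row)
    start, end = ref_core
    if not (1 <= start <= end <= len(ref_cols)):
        raise ValueError(
            f"core {ref_core} outside reference length {len(ref_cols)}"
        )
    c1, c2 = ref_cols[start - 1], ref_cols[end - 1]
    ref_core_len = end - start + 1

    annotations = []
    for rid, gapped in alignment.rows:
        cols = _column_map(gapped)
        length = len(cols)
        covered = [i for i, col in enumerate(cols) if c1 <= col <= c2]
        if not covered:
            logger.warning("row %s is all-gap across core columns; unsegmentable", rid)
            annotations.append(
                RegionAnnotation(rid, length, core=None, status="unsegmentable")
            )
            continue
        core_start, core_end = covered[0] + 1, covered[-1] + 1
        status = "ok"
        if (core_end - core_start + 1) < partial_fraction * ref_core_len:
            status = "partial"
            logger.info("row %s: projected core below %.0f%% of reference; partial",
                        rid, 100 * partial_fraction)
        annotations.append(
            RegionAnnotation(
                rid,
                length,
                core=(core_start, core_end),
                n_region=(1, core_start - 1) if core_start > 1 else None,
                c_region=(core_end + 1, length) if core_end < length else None,
                status=status,
            )
        )
    return annotations


def region_lengths(
    annotations: Sequence[RegionAnnotation],
    families: Mapping[str, str],
) -> pd.DataFrame:
    """Per family and region: mean, sd, min, max length (empty regions count 0).

    Only annotations with status "ok" contribute.  Requires at least one
    usable annotation per family present in ``families``.
    """
    rows = []
    for ann in annotations:
        if ann.status != "ok":
            continue
        fam = families.get(ann.protein_id)
        if fam is None:
            continue
        for region in REGIONS:
            rows.append({"family": fam, "region": region,
                         "length": ann.region_length(region)})
    if not rows:
        raise ValueError("no usable annotations")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["family", "region"], sort=True)["length"]
        .agg(mean="mean", sd="std", min="min", max="max", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def annotations_to_table(annotations: Sequence[RegionAnnotation]) -> pd.DataFrame:
    def _s(span, idx):
        return span[idx] if span is not None else 0

    return pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in annotations],
            "n_start": [_s(a.n_region, 0) for a in annotations],
            "n_end": [_s(a.n_region, 1) for a in annotations],
            "core_start": [_s(a.core, 0) for a in annotations],
            "core_end": [_s(a.core, 1) for a in annotations],
            "c_start": [_s(a.c_region, 0) for a in annotations],
            "c_end": [_s(a.c_region, 1) for a in annotations],
            "status": [a.status for a in annotations],
        }
    )


def table_to_annotations(df: pd.DataFrame, lengths: Mapping[str, int]) -> list[RegionAnnotation]:
    out = []
    for _, r in df.iterrows():
        pid = r["protein_id"]
        if r["status"] == "unsegmentable":
            out.append(RegionAnnotation(pid, lengths[pid], core=None, status="unsegmentable"))
            continue
        out.append(
            RegionAnnotation(
                pid,
                lengths[pid],
                core=(int(r["core_start"]), int(r["core_end"])),
                n_region=(int(r["n_start"]), int(r["n_end"])) if r["n_start"] else None,
                c_region=(int(r["c_start"]), int(r["c_end"])) if r["c_start"] else None,
                status=r["status"],
            )
        )
    return out
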