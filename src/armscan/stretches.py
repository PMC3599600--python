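"""Same-sign charged-stretch detection.

A stretch is a maximal span of same-sign charged residues (K/R positive,
D/E negative; His uncharged): either an uninterrupted run of at least three,
or a span with exactly one uncharged interior position in the CCXCC / CXCCCC
style — admitted from span 5 (>=4 charged) in strict mode, the default, and
from span 4 (>=3 charged, e.g. the DEGE form) in lenient mode.  An
opposite-sign residue can never serve as the interior gap.  Only maximal
spans are reported, never sub-stretches.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .seqio import SequenceRecord
from .segmentation import RegionAnnotation

_SIGN = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class ChargedStretch:
    protein_id: str
    sign: Literal["positive", "negative"]
    start: int  # 1-based inclusive
    end: int
    n_charged: int
    pattern: str  # literal matched subsequence

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _runs(signs: list[int], sign: int) -> list[tuple[int, int]]:
    """Maximal 0-based [start, end] runs of a given sign."""
    runs = []
    start = None
    for i, s in enumerate(signs):
        if s == sign:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(signs) - 1))
    return runs


def find_stretches(
    record: SequenceRecord | str,
    mode: Literal["strict", "lenient"] = "strict",
) -> list[ChargedStretch]:
    """All maximal charged stretches of both signs, sorted by start.

    Strict mode follows the >=3-run rule with one-gap spans admitted only from
    span 5; lenient mode additionally admits span-4 one-gap forms.  Candidate
    spans contained in a larger reported span are suppressed.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(record, SequenceRecord):
        pid, seq = record.id, record.residues
    else:
        pid, seq = "", record
    signs = [_SIGN.get(ch, 0) for ch in seq]
    min_gapped_span = 5 if mode == "strict" else 4

    hits: list[ChargedStretch] = []
    for sign, label in ((1, "positive"), (-1, "negative")):
        runs = _runs(signs, sign)
        candidates: list[tuple[int, int, int]] = []  # (start, end, n_charged)
        for start, end in runs:
            if end - start + 1 >= 3:
                candidates.append((start, end, end - start + 1))
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            if s2 - e1 == 2 and signs[e1 + 1] == 0:  # exactly one neutral between
                span = e2 - s1 + 1
                if span >= min_gapped_span:
                    candidates.append((s1, e2, span - 1))
        # suppress candidates contained in another candidate of the same sign
        maximal = [
            c
            for c in candidates
            if not any(
                (o[0] <= c[0] and c[1] <= o[1]) and o != c for o in candidates
            )
        ]
        hits.extend(
            ChargedStretch(pid, label, s + 1, e + 1, n, seq[s : e + 1])
            for s, e, n in maximal
        )
    hits.sort(key=lambda h: (h.start, h.end, h.sign))
    return hits


def stretch_summary(
    stretches: Sequence[ChargedStretch],
    annotations: Mapping[str, RegionAnnotation],
    families: Mapping[str, str],
) -> pd.DataFrame:
    """Counts of positive/negative stretches per family per region.

    Each stretch is assigned to the region containing its start; stretches
    spanning a region boundary are counted there but flagged.
    """
    rows = []
    for st in stretches:
        ann = annotations.get(st.protein_id)
        if ann is None or ann.status == "unsegmentable":
            continue
        region = ann.region_of(st.start)
        boundary = ann.region_of(st.end) != region
        rows.append(
            {
                "protein_id": st.protein_id,
                "family": families.get(st.protein_id),
                "region": region,
                "sign": st.sign,
                "start": st.start,
                "end": st.end,
                "pattern": st.pattern,
                "boundary": boundary,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=["protein_id", "family", "region", "sign", "start", "end",
                 "pattern", "boundary"],
    )
    if detail.empty:
        counts = pd.DataFrame(columns=["family", "region", "sign", "count"])
    else:
        counts = (
            detail.groupby(["family", "region", "sign"], sort=True)
            .size()
            .reset_index(name="count")
        )
    counts.attrs["detail"] = detail
    return counts
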