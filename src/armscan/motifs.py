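"""Sequence-pattern scanning, phospho-site proximity, and tandem repeats.

Patterns are PROSITE-like element lists — literal residues, residue classes
like [LIVFM] or (S/T), and variable spacers x(2,3).  The built-ins are the
leucine-rich nuclear export signal L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI], the
literal nuclear localisation signal RKKRKD, and the casein kinase II
acceptor consensus (S/T)-x-x-(D/E).  The scanner reports every distinct
(start, end) extent, overlapping matches included.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, SequenceRecord
from .segmentation import RegionAnnotation

_ANY = frozenset(AMINO_ACIDS + "X")  # 'x' spacers match any residue incl. X


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[tuple[frozenset[str], int, int], ...]  # (class, min, max)

    def __post_init__(self) -> None:
        for cls, lo, hi in self.elements:
            if not cls or lo > hi or lo < 0:
                raise ValueError(f"{self.name}: malformed element {(sorted(cls), lo, hi)}")

    @property
    def min_length(self) -> int:
        return sum(lo for _, lo, _ in self.elements)


_TOKEN = re.compile(
    r"^(?:(?P<x>x)|\[(?P<cls>[A-Z]+)\]|\((?P<alt>[A-Z](?:/[A-Z])+)\)|(?P<lit>[A-Z]))"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


def parse_pattern(name: str, text: str) -> MotifPattern:
    """Parse a PROSITE-like dash-separated pattern string.

    Examples: ``L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]``, ``(S/T)-x-x-(D/E)``,
    ``R-K-K-R-K-D``.
    """
    elements = []
    for token in text.replace(" ", "").split("-"):
        m = _TOKEN.match(token)
        if not m:
            raise ValueError(f"{name}: cannot parse pattern token {token!r}")
        if m.group("x"):
            cls = _ANY
        elif m.group("cls"):
            cls = frozenset(m.group("cls"))
        elif m.group("alt"):
            cls = frozenset(m.group("alt").split("/"))
        else:
            cls = frozenset(m.group("lit"))
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        elements.append((cls, lo, hi))
    return MotifPattern(name, tuple(elements))


NES = parse_pattern("NES", "L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]")
NLS = parse_pattern("NLS", "R-K-K-R-K-D")
CK2 = parse_pattern("CK2", "(S/T)-x-x-(D/E)")
BUILTIN_PATTERNS = {"NES": NES, "NLS": NLS, "CK2": CK2}


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    pattern: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    region: Optional[str] = None


@dataclass(frozen=True)
class PhosphoSite:
    protein_id: str
    position: int
    residue: str  # S, T or Y
    source: str  # scanner or track name


@dataclass(frozen=True)
class TandemRepeat:
    protein_id: str
    start: int  # 1-based inclusive
    unit_length: int
    copies: int
    identities: tuple[float, ...]  # per-copy identity to the consensus

    @property
    def span(self) -> int:
        return self.unit_length * self.copies

    @property
    def end(self) -> int:
        return self.start + self.span - 1

    @property
    def min_identity(self) -> float:
        return min(self.identities)


def scan_pattern(record: SequenceRecord | str, pattern: MotifPattern) -> list[MotifHit]:
    """All matches of ``pattern`` at every start, one hit per distinct extent.

    Variable-repeat elements are enumerated shortest-first; overlapping
    extents are all reported.
    """
    if isinstance(record, SequenceRecord):
        pid, seq = record.id, record.residues
    else:
        pid, seq = "", record
    n = len(seq)
    elements = pattern.elements
    hits: set[tuple[int, int]] = set()

    def extend(pos: int, elem_idx: int) -> set[int]:
        """Set of end offsets (exclusive) reachable matching elements[elem_idx:]."""
        if elem_idx == len(elements):
            return {pos}
        cls, lo, hi = elements[elem_idx]
        ends: set[int] = set()
        for rep in range(lo, hi + 1):
            if pos + rep > n:
                break
            if all(seq[pos + k] in cls for k in range(rep)):
                ends |= extend(pos + rep, elem_idx + 1)
        return ends

    for start in range(n - pattern.min_length + 1):
        for end in extend(start, 0):
            hits.add((start, end))
    return [
        MotifHit(pid, pattern.name, s + 1, e, seq[s:e])
        for s, e in sorted(hits)
    ]


def label_hits(hits: Sequence[MotifHit], annotations: Mapping[str, RegionAnnotation]) -> list[MotifHit]:
    """Attach the region label of each hit's start position."""
    out = []
    for h in hits:
        ann = annotations.get(h.protein_id)
        region = None
        if ann is not None and ann.status != "unsegmentable":
            region = ann.region_of(h.start)
        out.append(MotifHit(h.protein_id, h.pattern, h.start, h.end, h.matched, region))
    return out


def sites_from_hits(hits: Sequence[MotifHit], records: Mapping[str, SequenceRecord],
                    acceptor_offset: int = 0) -> list[PhosphoSite]:
    """Phospho-acceptor sites from kinase-consensus hits (acceptor = first residue)."""
    sites = []
    for h in hits:
        pos = h.start + acceptor_offset
        residue = records[h.protein_id].residues[pos - 1]
        sites.append(PhosphoSite(h.protein_id, pos, residue, source=h.pattern))
    return sorted(set(sites), key=lambda s: (s.protein_id, s.position))


def phospho_proximity(sites, stretches, window: int = 5) -> pd.DataFrame:
    """Distance from each phospho site to the nearest charged stretch.

    Distance is 0 inside a stretch, otherwise the residue gap to the nearest
    stretch end; ``near`` means distance <= window.  Sites and stretches are
    matched per protein.
    """
    by_protein: dict[str, list] = {}
    for st in stretches:
        by_protein.setdefault(st.protein_id, []).append(st)
    rows = []
    for site in sites:
        best = None
        for st in by_protein.get(site.protein_id, []):
            if st.start <= site.position <= st.end:
                d = 0
            elif site.position < st.start:
                d = st.start - site.position
            else:
                d = site.position - st.end
            if best is None or d < best[0]:
                best = (d, st)
        rows.append(
            {
                "protein_id": site.protein_id,
                "position": site.position,
                "residue": site.residue,
                "source": site.source,
                "stretch_start": best[1].start if best else None,
                "stretch_end": best[1].end if best else None,
                "stretch_sign": best[1].sign if best else None,
                "distance": best[0] if best else None,
                "near": bool(best and best[0] <= window),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "position", "residue", "source", "stretch_start",
                 "stretch_end", "stretch_sign", "distance", "near"],
    )


def _copy_identities(arr: np.ndarray, start: int, unit: int, copies: int) -> list[float]:
    block = arr[start : start + unit * copies].reshape(copies, unit)
    # column-majority consensus, ties broken by the first copy
    consensus = block[0].copy()
    if copies > 2:
        for col in range(unit):
            vals, counts = np.unique(block[:, col], return_counts=True)
            best = counts.max()
            if best > (block[:, col] == consensus[col]).sum():
                consensus[col] = vals[np.argmax(counts)]
    return [(block[k] == consensus).mean() for k in range(copies)]


def find_tandem_repeats(
    record: SequenceRecord | str,
    min_unit: int = 10,
    min_copies: int = 2,
    min_identity: float = 0.9,
    max_unit: Optional[int] = None,
) -> list[TandemRepeat]:
    """Maximal non-nested tandem repeats, longest span first.

    For each candidate period and start, copies are added while every copy
    keeps identity >= ``min_identity`` to the column-majority consensus of
    the copies.  Candidates whose span lies inside an already accepted span
    are suppressed.
    """
    if min_unit < 3 or min_copies < 2:
        raise ValueError("min_unit >= 3 and min_copies >= 2 required")
    if isinstance(record, SequenceRecord):
        pid, seq = record.id, record.residues
    else:
        pid, seq = "", record
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    hi = max_unit if max_unit is not None else n // min_copies
    candidates: list[TandemRepeat] = []
    pair_floor = max(0.0, 2 * min_identity - 1)  # adjacent-copy identity implied bound
    for unit in range(min_unit, hi + 1):
        if 2 * unit > n:
            break
        eq = arr[: n - unit] == arr[unit:]
        csum = np.concatenate([[0], np.cumsum(eq)])
        pair_id = (csum[unit:] - csum[:-unit]) / unit  # identity copy@s vs copy@s+unit
        for start in np.nonzero(pair_id >= pair_floor)[0]:
            copies = 2
            idents = _copy_identities(arr, start, unit, 2)
            if min(idents) < min_identity:
                continue
            while start + (copies + 1) * unit <= n:
                trial = _copy_identities(arr, start, unit, copies + 1)
                if min(trial) < min_identity:
                    break
                copies += 1
                idents = trial
            candidates.append(
                TandemRepeat(pid, int(start) + 1, unit, copies, tuple(idents))
            )
    candidates.sort(key=lambda r: (-r.span, -r.min_identity, r.start, r.unit_length))
    accepted: list[TandemRepeat] = []
    for cand in candidates:
        # suppress nested candidates and near-duplicate shifted phases: anything
        # sharing more than half its span with an already accepted repeat
        overlaps = (
            min(cand.end, a.end) - max(cand.start, a.start) + 1 for a in accepted
        )
        if any(ov > cand.span / 2 for ov in overlaps):
            continue
        accepted.append(cand)
    return accepted


def motif_presence(hits: Sequence[MotifHit], families: Mapping[str, str]) -> pd.DataFrame:
    """Collapse hits to family x region x pattern presence (Table-2 style)."""
    rows = [
        {"family": families.get(h.protein_id), "region": h.region, "pattern": h.pattern}
        for h in hits
        if h.region is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["family", "region", "pattern", "present"])
    df = pd.DataFrame(rows).drop_duplicates().sort_values(
        ["family", "region", "pattern"]
    )
    df["present"] = True
    return df.reset_index(drop=True)
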