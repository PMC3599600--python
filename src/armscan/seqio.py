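"""Sequence I/O and the shared data model.

Reads and writes the external formats used across the pipeline (protein and
nucleotide FASTA, aligned FASTA / CLUSTAL alignments, sidecar metadata TSV,
per-residue annotation tracks) and defines the record types every downstream
stage consumes.  Coordinates are 1-based inclusive everywhere they are
externally visible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class SeqioError(ValueError):
    """Raised on malformed input files or inconsistent records."""


@dataclass
class SequenceRecord:
    """One protein with its organism/family/rank metadata.

    ``rank`` is the position of the organism on the evolutionary x-axis used
    by the GC trend regressions; it is a non-negative integer, filled in by
    :func:`join_metadata`.
    """

    id: str
    residues: str
    organism: Optional[str] = None
    family: Optional[str] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise SeqioError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise SeqioError(
                    f"{self.id}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CodingRecord:
    """In-frame coding sequence paired with a protein by id."""

    protein_id: str
    nucleotides: str

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.nucleotides, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise SeqioError(
                    f"{self.protein_id}: illegal base {ch!r} at position {pos}"
                )
        if len(self.nucleotides) % 3 != 0:
            raise SeqioError(
                f"{self.protein_id}: CDS length {len(self.nucleotides)} "
                "not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class AlignmentBlock:
    """A multiple sequence alignment: ordered (id, gapped string) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SeqioError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise SeqioError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise SeqioError("alignment contains duplicate row ids")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def validate_against(self, records: Sequence[SequenceRecord]) -> None:
        """Check that ungapping each row reproduces the matching record."""
        by_id = {r.id: r for r in records}
        for rid, gapped in self.rows:
            rec = by_id.get(rid)
            if rec is not None and gapped.replace("-", "") != rec.residues:
                raise SeqioError(f"alignment row {rid} does not ungap to its record")


@dataclass
class AnnotationTrack:
    """External per-residue annotation (disorder binary string or phospho sites)."""

    protein_id: str
    kind: Literal["disorder", "phospho"]
    disorder: Optional[str] = None          # '0'/'1' string, one char per residue
    phospho: frozenset[int] = field(default_factory=frozenset)  # 1-based positions

    def validate_against(self, record: SequenceRecord) -> None:
        if self.kind == "disorder":
            if self.disorder is None or len(self.disorder) != len(record):
                raise SeqioError(
                    f"{self.protein_id}: disorder track length mismatch"
                )
            if set(self.disorder) - {"0", "1"}:
                raise SeqioError(f"{self.protein_id}: disorder track must be binary")
        else:
            for pos in self.phospho:
                if not 1 <= pos <= len(record):
                    raise SeqioError(f"{self.protein_id}: phospho position {pos} out of range")
                if record.residues[pos - 1] not in "STY":
                    raise SeqioError(
                        f"{self.protein_id}: phospho position {pos} is "
                        f"{record.residues[pos - 1]}, not S/T/Y"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: Literal["protein", "nucleotide"] = "protein"):
    """Read a FASTA file into SequenceRecord or CodingRecord objects.

    Records are returned in file order.  Duplicate ids and illegal characters
    are hard errors (named in the exception).
    """
    path = Path(path)
    if not path.exists():
        raise SeqioError(f"no such file: {path}")
    seen: set[str] = set()
    out = []
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SeqioError(f"duplicate id {bio.id!r} in {path}")
        seen.add(bio.id)
        seq = str(bio.seq).upper()
        if kind == "protein":
            out.append(SequenceRecord(id=bio.id, residues=seq))
        else:
            out.append(CodingRecord(protein_id=bio.id, nucleotides=seq))
    return out


def write_fasta(records: Iterable[SequenceRecord | CodingRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column wrapping (round-trip safe)."""
    bio_records = []
    for rec in records:
        if isinstance(rec, SequenceRecord):
            bio_records.append(_BioSeqRecord(Seq(rec.residues), id=rec.id, description=""))
        else:
            bio_records.append(_BioSeqRecord(Seq(rec.nucleotides), id=rec.protein_id, description=""))
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(path: str | Path, fmt: Optional[str] = None) -> AlignmentBlock:
    """Read an aligned FASTA or CLUSTAL file.

    When ``fmt`` is None the dialect is guessed from the first non-blank line
    (CLUSTAL header vs '>').
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = ""
            for line in fh:
                if line.strip():
                    first = line
                    break
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return AlignmentBlock(rows=[(r.id, str(r.seq).upper()) for r in aln])


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, gapped in block.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), 60):
                fh.write(gapped[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Metadata and annotation tables


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "organism": str, "family": str})
    required = {"id", "organism", "family", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise SeqioError(f"metadata table missing columns: {sorted(missing)}")
    return df


def join_metadata(records: Sequence[SequenceRecord], metadata: pd.DataFrame | str | Path):
    """Populate organism/family/rank from the sidecar table.

    Records absent from the table are logged and dropped; a negative or
    non-integer rank, or a duplicated table id, is an error.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    if metadata["id"].duplicated().any():
        dup = metadata.loc[metadata["id"].duplicated(), "id"].iloc[0]
        raise SeqioError(f"metadata id collision: {dup!r}")
    ranks = {}
    for _, row in metadata.iterrows():
        try:
            rank = int(row["rank"])
        except (TypeError, ValueError):
            raise SeqioError(f"rank {row['rank']!r} for {row['id']} is not an integer")
        if rank < 0 or rank != float(row["rank"]):
            raise SeqioError(f"rank {row['rank']!r} for {row['id']} is not a non-negative integer")
        ranks[row["id"]] = (row["organism"], row["family"], rank)
    joined = []
    for rec in records:
        if rec.id not in ranks:
            logger.warning("record %s absent from metadata table; dropped", rec.id)
            continue
        organism, family, rank = ranks[rec.id]
        joined.append(replace(rec, organism=organism, family=family, rank=rank))
    return joined


def write_metadata(records: Sequence[SequenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "organism": [r.organism for r in records],
            "family": [r.family for r in records],
            "rank": [r.rank for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> list[AnnotationTrack]:
    """Read annotation tracks: TSV columns protein_id, kind, payload.

    Payload is a 0/1 string for disorder tracks and a comma-separated list of
    1-based positions for phospho tracks.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "kind", "payload"}
    if required - set(df.columns):
        raise SeqioError(f"annotation table must have columns {sorted(required)}")
    tracks = []
    for _, row in df.iterrows():
        kind = row["kind"]
        if kind == "disorder":
            tracks.append(AnnotationTrack(row["protein_id"], "disorder", disorder=row["payload"]))
        elif kind == "phospho":
            positions = frozenset(int(p) for p in str(row["payload"]).split(",") if p)
            tracks.append(AnnotationTrack(row["protein_id"], "phospho", phospho=positions))
        else:
            raise SeqioError(f"unknown track kind {kind!r}")
    return tracks


# ---------------------------------------------------------------------------
# CDS pairing


def _translate(cds: str) -> str:
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def pair_cds(
    proteins: Sequence[SequenceRecord],
    cds_records: Sequence[CodingRecord],
    validate: bool = True,
) -> list[tuple[SequenceRecord, CodingRecord]]:
    """Pair proteins with their coding sequences by id.

    With ``validate`` on, the standard-code translation of the CDS (trailing
    stop ignored) must equal the protein, with 'X' wildcards on either side
    permitted; a mismatch is an error naming the first discordant codon.
    Unmatched CDS ids are warnings and are skipped.
    """
    prot_by_id = {p.id: p for p in proteins}
    pairs = []
    for cds in cds_records:
        prot = prot_by_id.get(cds.protein_id)
        if prot is None:
            logger.warning("CDS %s has no matching protein; skipped", cds.protein_id)
            continue
        if validate:
            translated = _translate(cds.nucleotides)
            if len(translated) != len(prot.residues):
                raise SeqioError(
                    f"{cds.protein_id}: CDS encodes {len(translated)} residues, "
                    f"protein has {len(prot.residues)}"
                )
            for i, (got, want) in enumerate(zip(translated, prot.residues), start=1):
                if got != want and want != "X" and got != "X":
                    raise SeqioError(
                        f"{cds.protein_id}: translation mismatch at codon {i} "
                        f"({got} != {want})"
                    )
        pairs.append((prot, cds))
    return pairs
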