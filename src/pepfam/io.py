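"""Readers and writers for every external format the pipeline touches.

FASTA headers follow the common ``>id product description`` convention: the
first whitespace splits the unique id from the optional free-text product.
Hit tables are BLAST tabular: the standard 12-column ``outfmt 6`` dialect, or
a 14-column extension that appends query and subject lengths (needed to
compute alignment coverage without the source FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

STANDARD12 = "standard12"
EXTENDED14 = "extended14"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One small protein: id, residue sequence and optional annotations."""

    id: str
    sequence: str
    product: str | None = None
    taxon: str | None = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("protein id must be non-empty")
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-alphabet characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class HitTableRow:
    """One directed pairwise alignment hit (BLAST tabular conventions).

    Coordinates are 1-based inclusive.  ``q_len``/``s_len`` may be ``None``
    for 12-column input until filled from the FASTA.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    q_len: int | None = None
    s_len: int | None = None

    def __post_init__(self):
        if self.alignment_length < 1:
            raise FormatError("alignment_length must be >= 1")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError("start must not exceed end in a protein local alignment")

    @property
    def q_coverage(self) -> float:
        if self.q_len is None:
            raise ValueError("q_len unknown; fill lengths from FASTA first")
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def s_coverage(self) -> float:
        if self.s_len is None:
            raise ValueError("s_len unknown; fill lengths from FASTA first")
        return (self.s_end - self.s_start + 1) / self.s_len


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; header = ``id`` + optional product after whitespace."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        desc = rec.description
        product = None
        if desc.startswith(rid):
            rest = desc[len(rid):].strip()
            product = rest or None
        records.append(ProteinRecord(id=rid, sequence=str(rec.seq).upper(), product=product))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.product is None else f"{rec.id} {rec.product}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_HIT_COLUMNS = 12


def read_hits_table(path: str | Path, dialect: str = STANDARD12) -> list[HitTableRow]:
    """Parse a BLAST-style tabular hit file (12- or 14-column)."""
    if dialect not in (STANDARD12, EXTENDED14):
        raise ValueError(f"unknown dialect {dialect!r}")
    want = _HIT_COLUMNS + (2 if dialect == EXTENDED14 else 0)
    rows: list[HitTableRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != want:
                raise FormatError(
                    f"{path}: line {lineno}: expected {want} columns, found {len(parts)}"
                )
            try:
                row = HitTableRow(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                    q_len=int(parts[12]) if want == 14 else None,
                    s_len=int(parts[13]) if want == 14 else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            rows.append(row)
    return rows


def write_hits_table(rows: Iterable[HitTableRow], path: str | Path) -> None:
    """Write hits in the 14-column dialect (lengths required)."""
    with open(path, "w") as fh:
        for r in rows:
            if r.q_len is None or r.s_len is None:
                raise ValueError("cannot write extended14 without q_len/s_len")
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.2f}",
                        str(r.alignment_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.e_value:.3e}",
                        f"{r.bit_score:.4f}",
                        str(r.q_len),
                        str(r.s_len),
                    ]
                )
                + "\n"
            )


def fill_lengths(rows: Sequence[HitTableRow], records: Iterable[ProteinRecord]) -> list[HitTableRow]:
    """Fill q_len/s_len of 12-column rows from the FASTA records."""
    lengths = {r.id: len(r.sequence) for r in records}
    out = []
    for row in rows:
        try:
            out.append(
                replace(row, q_len=lengths[row.query_id], s_len=lengths[row.subject_id])
            )
        except KeyError as exc:
            raise FormatError(f"hit references unknown protein id {exc}") from None
    return out


# --- alignments ------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: parallel ids and equal-length rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise FormatError("ragged alignment: rows differ in length")

    def ungapped(self, index: int) -> str:
        return self.rows[index].replace("-", "").replace(".", "")


def write_alignment(msa: Msa, path: str | Path, format: str = "afa") -> None:
    """Write an alignment as aligned FASTA (``afa``) or ``stockholm``."""
    if format == "afa":
        with open(path, "w") as fh:
            for rid, row in zip(msa.ids, msa.rows):
                fh.write(f">{rid}\n{row}\n")
    elif format == "stockholm":
        width = max((len(i) for i in msa.ids), default=0)
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for rid, row in zip(msa.ids, msa.rows):
                fh.write(f"{rid:<{width}}  {row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def read_alignment(path: str | Path, format: str = "afa") -> Msa:
    if format == "afa":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return Msa(tuple(ids), tuple(rows))
    if format == "stockholm":
        ids, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "//")):
                    continue
                rid, row = line.split(None, 1)
                ids.append(rid)
                rows.append(row.strip())
        return Msa(tuple(ids), tuple(rows))
    raise ValueError(f"unknown alignment format {format!r}")


def write_families_tsv(families: Sequence["Family"], path: str | Path) -> None:
    """Write member and summary tables for called families.

    Families are ordered by descending size, then family id; members
    lexicographically.  ``<path>`` receives the member table and
    ``<path stem>.summary.tsv`` the per-family summary.
    """
    from .families import Family  # local import to avoid a cycle

    path = Path(path)
    ordered = sorted(families, key=lambda f: (-len(f.member_ids), f.family_id))
    with open(path, "w") as fh:
        fh.write("family_id\tmember_id\n")
        for fam in ordered:
            for mid in sorted(fam.member_ids):
                fh.write(f"{fam.family_id}\t{mid}\n")
    summary = path.with_suffix(".summary.tsv")
    with open(summary, "w") as fh:
        fh.write("family_id\tsize\tproduct\tgathering_cutoff\tmean_member_length\n")
        for fam in ordered:
            mean_len = sum(fam.member_lengths.values()) / len(fam.member_lengths)
            fh.write(
                f"{fam.family_id}\t{len(fam.member_ids)}\t"
                f"{fam.product or ''}\t{fam.gathering_cutoff:.4f}\t{mean_len:.2f}\n"
            )
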