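"""Sequence and alignment data model with standard-format I/O.

Protein records use the 20 standard amino acids plus ``X`` (unknown).
Coordinates are 1-based throughout and spans are inclusive, matching the
peptide-fragment naming convention of the field (e.g. "ANAC013(254-274)").
The only gap character is ``-``; ``.`` on input is normalised to ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class SequenceError(ValueError):
    """Raised for records violating the protein-sequence contract."""


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, missing ids...)."""


@dataclass(frozen=True)
class Sequence:
    """An ungapped protein sequence.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Upper-case amino-acid string; alphabet ``ACDEFGHIKLMNPQRSTVWXY``.
    species_tag : str or None
        Optional short species prefix (e.g. ``"AT"``, ``"PP"``).
    """

    id: str
    residues: str
    species_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - ALPHABET
        if GAP in self.residues or "." in self.residues:
            raise SequenceError(f"{self.id}: gap characters not allowed in unaligned sequence")
        if bad:
            raise SequenceError(f"{self.id}: illegal residue(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GappedRow:
    id: str
    gapped: str
    species_tag: str | None = None

    def degap(self) -> Sequence:
        return Sequence(self.id, self.gapped.replace(GAP, ""), self.species_tag)


class CoordinateMap:
    """Bijection between 1-based ungapped residue index and alignment column
    for one alignment row; strictly increasing in both directions."""

    def __init__(self, gapped: str):
        self._res2col: list[int] = [
            col for col, ch in enumerate(gapped, start=1) if ch != GAP
        ]
        self._col2res: dict[int, int] = {
            col: res for res, col in enumerate(self._res2col, start=1)
        }
        self.ncol = len(gapped)

    @property
    def nres(self) -> int:
        return len(self._res2col)

    def to_column(self, residue_index: int) -> int:
        if not 1 <= residue_index <= self.nres:
            raise IndexError(f"residue index {residue_index} out of range 1..{self.nres}")
        return self._res2col[residue_index - 1]

    def to_residue(self, column: int) -> int | None:
        """Residue index at ``column`` or None when the row is gapped there."""
        if not 1 <= column <= self.ncol:
            raise IndexError(f"column {column} out of range 1..{self.ncol}")
        return self._col2res.get(column)


@dataclass
class Alignment:
    """A gapped protein family alignment (gap character ``-``)."""

    rows: list[GappedRow]
    ncol: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        lengths = {len(r.gapped) for r in self.rows}
        if len(lengths) != 1:
            bad = sorted({r.id for r in self.rows})
            raise AlignmentError(f"ragged alignment rows: {bad}")
        self.ncol = lengths.pop()
        self._by_id = {r.id: r for r in self.rows}
        if len(self._by_id) != len(self.rows):
            raise AlignmentError("duplicate row ids in alignment")
        self._maps = {r.id: CoordinateMap(r.gapped) for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> GappedRow:
        try:
            return self._by_id[row_id]
        except KeyError:
            raise AlignmentError(f"no row with id {row_id!r}") from None

    def coordinate_map(self, row_id: str) -> CoordinateMap:
        self.row(row_id)
        return self._maps[row_id]

    def sequences(self) -> list[Sequence]:
        return [r.degap() for r in self.rows]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _species_tag(identifier: str) -> str | None:
    # Ortholog ids often carry a leading upper-case species prefix ("AT...", "PP...").
    head = identifier[:2]
    if len(head) == 2 and head.isalpha() and head.isupper():
        return head
    return None


def read_fasta(path) -> list[Sequence]:
    """Read unaligned protein FASTA. Gaps in records are an error."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = str(rec.seq)
        if not rec.id:
            raise SequenceError(f"{path}: record with empty header")
        try:
            out.append(Sequence(rec.id, residues.replace(".", GAP), _species_tag(rec.id)))
        except SequenceError as exc:
            raise SequenceError(f"{path}: {exc}") from exc
    return out


def write_fasta(sequences: Iterable[Sequence], path) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_alignment(path, dialect: str = "afa") -> Alignment:
    """Read an alignment in aligned-FASTA (``afa``) or ``clustal`` format."""
    fmt = {"afa": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r} (use 'afa' or 'clustal')")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    rows = [
        GappedRow(rec.id, str(rec.seq).upper().replace(".", GAP), _species_tag(rec.id))
        for rec in msa
    ]
    aln = Alignment(rows)
    for row in aln.rows:
        row.degap()  # validates residue alphabet
    return aln


def write_alignment(alignment: Alignment, path) -> None:
    """Alignments are always written as aligned FASTA."""
    recs = [SeqRecord(Seq(r.gapped), id=r.id, description="") for r in alignment.rows]
    with open(path, "w") as fh:
        AlignIO.write(MultipleSeqAlignment(recs), fh, "fasta")


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def map_region(alignment: Alignment, row_id: str, residue_span: tuple[int, int]) -> tuple[int, int]:
    """Map an inclusive 1-based residue span of one row to alignment columns."""
    lo, hi = residue_span
    if lo > hi:
        raise ValueError(f"empty span {residue_span}")
    cmap = alignment.coordinate_map(row_id)
    return cmap.to_column(lo), cmap.to_column(hi)


def unmap_region(alignment: Alignment, row_id: str, column_span: tuple[int, int]) -> tuple[int, int] | None:
    """Inverse of :func:`map_region`: columns that are gaps in the row are
    dropped; returns None when the row is entirely gapped over the span."""
    lo, hi = column_span
    if lo > hi:
        raise ValueError(f"empty span {column_span}")
    cmap = alignment.coordinate_map(row_id)
    residues = [r for c in range(lo, hi + 1) if (r := cmap.to_residue(c)) is not None]
    if not residues:
        return None
    return residues[0], residues[-1]
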