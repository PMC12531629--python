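"""Core sequence containers shared by every pipeline stage.

The pipeline works on amino-acid domain sequences.  A :class:`SequenceRecord`
is one (possibly gapped) sequence with its genome/taxon metadata; an
:class:`Alignment` is an ordered set of equal-length gapped records.  Columns
are addressed 1-based at the public surface, matching the convention of
ancestral-state tables and reference residue lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: The 20 standard amino acids in alphabetical one-letter order.  This order
#: is load-bearing: posterior vectors, PSSM columns and state files all index
#: residues by it.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

GAP = "-"
#: 'X' (ambiguous residue) is accepted on input and treated as a gap by every
#: scorer and by the likelihood machinery (missing data).
ALLOWED_SYMBOLS = frozenset(AMINO_ACIDS) | {GAP, "X"}


class RecordError(ValueError):
    """Raised for malformed or inconsistent sequence records."""


@dataclass
class SequenceRecord:
    """One amino-acid sequence with its provenance metadata.

    Parameters
    ----------
    id:
        Unique identifier (FASTA header token before the first whitespace).
    residues:
        Sequence over the 20 amino acids plus ``'-'`` (gap) and ``'X'``.
    genome_id:
        Identifier of the genome the protein comes from (one genome may
        contribute several family members).
    taxon:
        Optional taxonomic annotation.
    annotations:
        Optional set of orthology tags (e.g. ``{"crp"}``) used by the
        classifier's annotation-mixture rule.
    """

    id: str
    residues: str
    genome_id: str = ""
    taxon: str | None = None
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("sequence id must be nonempty")
        if not self.residues:
            raise RecordError(f"sequence {self.id!r} is empty")
        for pos, sym in enumerate(self.residues, start=1):
            if sym not in ALLOWED_SYMBOLS:
                raise RecordError(
                    f"sequence {self.id!r}: illegal residue symbol {sym!r} "
                    f"at position {pos}"
                )
        self.annotations = frozenset(self.annotations)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    @property
    def gap_fraction(self) -> float:
        return self.residues.count(GAP) / len(self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        """Copy of this record with a replaced sequence string."""
        return SequenceRecord(
            id=self.id,
            residues=residues,
            genome_id=self.genome_id,
            taxon=self.taxon,
            annotations=self.annotations,
        )


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise RecordError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


class Alignment:
    """Equal-length gapped rows keyed by sequence id.

    Invariants: all rows are exactly ``n_cols`` long, every row carries at
    least one non-gap symbol, and ids are unique.  Column indices are 1-based
    at the public surface.
    """

    def __init__(self, rows: Iterable[SequenceRecord]):
        self.rows: list[SequenceRecord] = list(rows)
        if not self.rows:
            raise RecordError("alignment must contain at least one row")
        check_unique_ids(self.rows)
        self.n_cols = len(self.rows[0].residues)
        for rec in self.rows:
            if len(rec.residues) != self.n_cols:
                raise RecordError(
                    f"row {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {self.n_cols}"
                )
            if rec.ungapped_length == 0:
                raise RecordError(f"row {rec.id!r} is all gaps")
        self._by_id = {rec.id: rec for rec in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.rows)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.rows]

    def get(self, seq_id: str) -> SequenceRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"no row with id {seq_id!r}") from None

    def column(self, col: int) -> str:
        """Symbols of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(rec.residues[col - 1] for rec in self.rows)

    def column_gap_fraction(self, col: int) -> float:
        c = self.column(col)
        return c.count(GAP) / len(c)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Rows restricted to ``ids``, preserving alignment row order."""
        keep = set(ids)
        return Alignment(rec for rec in self.rows if rec.id in keep)

    def drop_allgap_columns(self) -> "Alignment":
        keep = [
            c
            for c in range(self.n_cols)
            if any(rec.residues[c] != GAP for rec in self.rows)
        ]
        return Alignment(
            rec.with_residues("".join(rec.residues[c] for c in keep))
            for rec in self.rows
        )
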