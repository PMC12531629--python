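"""Iterative pruning/exclusion alignment curation.

Domain sets harvested from many genomes contain over-long outliers and
fragmentary, gap-inducing sequences that degrade a multiple alignment.  The
curation loop removes extremely long sequences once, then alternates
alignment with removal of rows that are themselves gap-rich or that park
most of their residues in otherwise-gappy columns, until the alignment is a
fixed point or the iteration budget is spent.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Callable, Sequence

from .align import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, progressive_align
from .records import Alignment, GAP, SequenceRecord


class CurationError(ValueError):
    pass


@dataclass
class CurationParams:
    """Thresholds of the pruning/exclusion loop.

    ``length_factor``: a sequence is "extremely long" if its ungapped length
    exceeds this multiple of the median ungapped length.  ``seq_gap_frac``:
    maximum tolerated per-row gap fraction.  ``col_gap_frac``: a column with
    at least this gap fraction is a "gappy column".
    ``gappy_contribution_frac``: a row is removed when at least this
    fraction of its non-gap symbols fall in gappy columns.  The gap
    penalties parameterise the internal aligner.
    """

    length_factor: float = 1.5
    seq_gap_frac: float = 0.5
    col_gap_frac: float = 0.8
    gappy_contribution_frac: float = 0.5
    max_iter: int = 5
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        for name in ("seq_gap_frac", "col_gap_frac", "gappy_contribution_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise CurationError(f"{name} must lie in (0, 1], got {v}")
        if self.length_factor <= 0:
            raise CurationError("length_factor must be > 0")
        if self.max_iter < 1:
            raise CurationError("max_iter must be >= 1")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise CurationError("gap penalties must be <= 0")


@dataclass
class CurationReport:
    removed_long: list[str] = field(default_factory=list)
    removed_gappy: list[list[str]] = field(default_factory=list)
    n_iterations: int = 0
    final_n_rows: int = 0
    final_n_cols: int = 0

    def to_rows(self) -> list[dict]:
        rows = [
            {"stage": "long", "iteration": 0, "id": i} for i in self.removed_long
        ]
        for it, ids in enumerate(self.removed_gappy, start=1):
            rows += [{"stage": "gappy", "iteration": it, "id": i} for i in ids]
        return rows


def remove_long_sequences(
    seqs: Sequence[SequenceRecord], params: CurationParams
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split off sequences longer than length_factor x median ungapped length."""
    seqs = list(seqs)
    if len(seqs) < 2:
        raise CurationError("need at least 2 sequences")
    med = median(rec.ungapped_length for rec in seqs)
    cut = params.length_factor * med
    kept = [r for r in seqs if r.ungapped_length <= cut]
    removed = [r for r in seqs if r.ungapped_length > cut]
    if not kept:
        raise CurationError("length threshold removed every sequence")
    return kept, removed


def prune_gappy(
    alignment: Alignment, params: CurationParams
) -> tuple[Alignment, list[str]]:
    """Remove gap-rich and gappy-column-contributing rows, drop empty columns.

    A column is gappy when its gap fraction is at least ``col_gap_frac``.
    A row goes when (a) its own gap fraction exceeds ``seq_gap_frac`` or
    (b) at least ``gappy_contribution_frac`` of its non-gap symbols sit in
    gappy columns.  All-gap columns are then deleted.
    """
    gappy_cols = {
        c
        for c in range(1, alignment.n_cols + 1)
        if alignment.column_gap_fraction(c) >= params.col_gap_frac
    }
    removed: list[str] = []
    for rec in alignment:
        if rec.gap_fraction > params.seq_gap_frac:
            removed.append(rec.id)
            continue
        non_gap = [c for c in range(1, alignment.n_cols + 1) if rec.residues[c - 1] != GAP]
        in_gappy = sum(1 for c in non_gap if c in gappy_cols)
        if non_gap and in_gappy / len(non_gap) >= params.gappy_contribution_frac:
            removed.append(rec.id)
    survivors = [r.id for r in alignment if r.id not in set(removed)]
    if len(survivors) < 2:
        raise CurationError("pruning would leave fewer than 2 rows")
    pruned = alignment.subset(survivors).drop_allgap_columns()
    return pruned, removed


Aligner = Callable[[list[SequenceRecord]], Alignment]


def external_aligner(command_template: str) -> Aligner:
    """Hook for running an external alignment tool.

    ``command_template`` must contain ``{in}`` and ``{out}`` placeholders
    for FASTA paths, e.g. ``"mafft --auto {in} > {out}"``.  Used for
    fidelity runs; the internal progressive aligner is the default.
    """

    def run(seqs: list[SequenceRecord]) -> Alignment:
        from .seqio import read_fasta, write_fasta

        with tempfile.TemporaryDirectory() as tmp:
            fin = Path(tmp) / "in.fasta"
            fout = Path(tmp) / "out.fasta"
            write_fasta([r.with_residues(r.ungapped) for r in seqs], fin)
            cmd = command_template.format(**{"in": str(fin), "out": str(fout)})
            subprocess.run(cmd, shell=True, check=True)
            by_id = {r.id: r for r in seqs}
            return Alignment(
                by_id[r.id].with_residues(r.residues) for r in read_fasta(fout)
            )

    return run


def curate_iterative(
    seqs: Sequence[SequenceRecord],
    params: CurationParams | None = None,
    aligner: Aligner | None = None,
) -> tuple[Alignment, CurationReport]:
    """Full curation loop: length filter once, then align/prune to a fixed point."""
    params = params or CurationParams()
    if len(seqs) < 3:
        raise CurationError("need at least 3 sequences")
    if aligner is None:

        def aligner(s: list[SequenceRecord]) -> Alignment:
            return progressive_align(
                s, gap_open=params.gap_open, gap_extend=params.gap_extend
            )

    report = CurationReport()
    kept, removed = remove_long_sequences(seqs, params)
    report.removed_long = [r.id for r in removed]

    current = [r.with_residues(r.ungapped) for r in kept]
    alignment = aligner(current)
    for it in range(1, params.max_iter + 1):
        report.n_iterations = it
        alignment, dropped = prune_gappy(alignment, params)
        report.removed_gappy.append(dropped)
        if not dropped or it == params.max_iter:
            break
        current = [r.with_residues(r.ungapped) for r in alignment]
        alignment = aligner(current)
    report.final_n_rows = len(alignment)
    report.final_n_cols = alignment.n_cols
    return alignment, report
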