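"""Reference-anchored conservation scoring of functional residue sets.

This is the analytical core of the package.  A *reference residue set* is a
small list of functionally characterised residues (e.g. the RNA-polymerase
contact patch AR1, or the DNA base-contact residues) given as 1-based
positions on an ungapped reference protein.  Those positions are mapped onto
the columns of a family alignment through the reference row, and every
extant or reconstructed ancestral sequence is scored there under two
schemes:

* a log-odds PSSM built from the reference row(s) with background-
  proportional pseudocounts (base-2 logs), and
* direct BLOSUM62 substitution scores against the reference residues, with
  the alphabet extended by a gap state carrying a fixed penalty (-0.12 by
  default), i.e. an n x 21 realised scoring matrix.

Scores are summed over the set (``raw``), divided by the set size
(``per_residue``), binned into four categories, paired across interface
partners per genome, and reduced to the best-scoring protein per genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .records import AMINO_ACIDS, GAP, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_GAP_PENALTY = -0.12
BIN_NAMES = ("extremely_low", "low", "medium", "high")
CATEGORIES = ("AR1", "phosphate_backbone", "specific_base", "det287", "custom")


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference residue sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceResidueSet:
    """Named category of reference residues on an ungapped reference.

    ``entries`` are (1-based position, one-letter residue) pairs with
    strictly increasing positions; ``n`` is the set size used to normalise
    raw scores.
    """

    category: str
    reference_id: str
    entries: tuple[tuple[int, str], ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ScoringError(f"{self.category}: reference set must be nonempty")
        last = 0
        for pos, res in self.entries:
            if pos <= last:
                raise ScoringError(
                    f"{self.category}: positions must be strictly increasing "
                    f"(got {pos} after {last})"
                )
            if res not in AMINO_ACIDS:
                raise ScoringError(
                    f"{self.category}: invalid residue {res!r} at position {pos}"
                )
            last = pos

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.entries)

    @property
    def residues(self) -> str:
        return "".join(r for _, r in self.entries)


def read_reference_sets(path) -> dict[str, ReferenceResidueSet]:
    """Read reference sets from TSV: category, reference_id, position, residue."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = ["category", "reference_id", "position", "residue"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ScoringError(f"reference-set table {path} lacks columns {missing}")
    out: dict[str, ReferenceResidueSet] = {}
    for (cat, ref_id), grp in df.groupby(["category", "reference_id"], sort=False):
        entries = tuple(
            sorted((int(r.position), str(r.residue)) for r in grp.itertuples())
        )
        out[str(cat)] = ReferenceResidueSet(
            category=str(cat), reference_id=str(ref_id), entries=entries
        )
    if not out:
        raise ScoringError(f"no reference sets in {path}")
    return out


def write_reference_sets(refsets: Mapping[str, ReferenceResidueSet], path) -> None:
    rows = [
        {
            "category": rs.category,
            "reference_id": rs.reference_id,
            "position": pos,
            "residue": res,
        }
        for rs in refsets.values()
        for pos, res in rs.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_table1() -> dict[str, ReferenceResidueSet]:
    """Packaged key functional residue sets of E. coli CRP.

    Three categories on the mature-chain numbering of E. coli CRP
    (initiator Met removed): ``AR1`` (11 residues, Pro154..Gln164),
    ``phosphate_backbone`` (7 residues) and ``specific_base`` (3 residues).
    The AR1 set is kept exactly as tabulated in the source literature, which
    lists 11 residues while describing AR1 in prose as ten; the discrepancy
    is recorded in the set's ``notes`` rather than resolved by dropping one.
    """
    ref = resources.files("hthcons.data").joinpath("table1.tsv")
    with resources.as_file(ref) as p:
        sets = read_reference_sets(p)
    sets["AR1"] = replace(
        sets["AR1"],
        notes=(
            "tabulated as 11 residues (Pro154..Gln164) although AR1 is "
            "described in prose as a ten-residue patch; kept as tabulated"
        ),
    )
    return sets


def ecocrp_reference() -> SequenceRecord:
    """Packaged E. coli CRP reference sequence (mature chain, 209 aa)."""
    from .seqio import read_fasta  # local import: seqio imports records only

    ref = resources.files("hthcons.data").joinpath("ecocrp.fasta")
    with resources.as_file(ref) as p:
        return read_fasta(p)[0]


# ---------------------------------------------------------------------------
# Column mapping
# ---------------------------------------------------------------------------


def map_reference_positions(
    alignment: Alignment, ref_set: ReferenceResidueSet
) -> list[int]:
    """Map reference positions to 1-based alignment columns.

    Column k corresponds to ungapped reference position p when the p-th
    non-gap symbol of the reference row sits in column k.  A mapped column
    whose reference residue differs from the expected one is reported with
    a warning (the mapping is still returned).
    """
    if ref_set.reference_id not in alignment:
        raise ScoringError(
            f"reference sequence {ref_set.reference_id!r} absent from alignment"
        )
    row = alignment.get(ref_set.reference_id).residues
    pos_to_col: dict[int, int] = {}
    p = 0
    for k, sym in enumerate(row, start=1):
        if sym != GAP:
            p += 1
            pos_to_col[p] = k
    columns = []
    for pos, res in ref_set.entries:
        if pos not in pos_to_col:
            raise ScoringError(
                f"{ref_set.category}: position {pos} beyond reference "
                f"ungapped length {p}"
            )
        col = pos_to_col[pos]
        found = row[col - 1]
        if found != res:
            logger.warning(
                "%s: reference residue at position %d is %r, expected %r",
                ref_set.category,
                pos,
                found,
                res,
            )
        columns.append(col)
    return columns


# ---------------------------------------------------------------------------
# PSSM scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pssm:
    """Log-odds matrix over reference-defined columns.

    ``matrix[i, a] = log2(p_a / q_a)`` with
    ``p_a = (c_a + beta * q_a) / (N + beta)``, where ``c_a`` counts residue
    ``a`` at column i over the N reference rows, ``q`` is the background and
    ``beta`` the pseudocount weight.  Gap/'X' symbols score ``gap_penalty``.
    """

    columns: tuple[int, ...]
    matrix: np.ndarray  # (n, 20), log2 odds
    background: np.ndarray  # (20,)
    beta: float
    gap_penalty: float = DEFAULT_GAP_PENALTY

    @property
    def n(self) -> int:
        return len(self.columns)


def build_pssm(
    reference_rows: Sequence[SequenceRecord | str],
    columns: Sequence[int],
    background: np.ndarray | None = None,
    beta: float = 1.0,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> Pssm:
    """Build the log-odds PSSM from aligned reference rows at ``columns``."""
    if not reference_rows:
        raise ScoringError("need at least one reference row")
    if beta < 0:
        raise ScoringError("pseudocount weight beta must be >= 0")
    rows = [
        r.residues if isinstance(r, SequenceRecord) else str(r)
        for r in reference_rows
    ]
    if background is None:
        background = np.full(20, 0.05)
    q = np.asarray(background, dtype=float)
    q = q / q.sum()
    N = len(rows)
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    M = np.empty((len(columns), 20))
    for i, col in enumerate(columns):
        counts = np.zeros(20)
        any_residue = False
        for row in rows:
            if col < 1 or col > len(row):
                raise ScoringError(f"column {col} out of range for reference row")
            sym = row[col - 1]
            if sym in idx:
                counts[idx[sym]] += 1
                any_residue = True
        if not any_residue:
            raise ScoringError(
                f"column {col} is entirely gapped in the reference set"
            )
        p = (counts + beta * q) / (N + beta)
        with np.errstate(divide="ignore"):
            M[i] = np.log2(p / q)
    return Pssm(
        columns=tuple(int(c) for c in columns),
        matrix=M,
        background=q,
        beta=beta,
        gap_penalty=gap_penalty,
    )


# ---------------------------------------------------------------------------
# Conservation scores
# ---------------------------------------------------------------------------


@dataclass
class ConservationScore:
    id: str
    category: str
    raw: float
    per_residue: float
    bin: str | None = None
    genome_id: str = ""


def score_pssm(
    pssm: Pssm,
    record: SequenceRecord,
    category: str = "custom",
) -> ConservationScore:
    """Score one aligned row under the PSSM (gaps/'X' score the gap penalty)."""
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    raw = 0.0
    for i, col in enumerate(pssm.columns):
        if col < 1 or col > len(record.residues):
            raise ScoringError(
                f"column {col} out of range for row {record.id!r}"
            )
        sym = record.residues[col - 1]
        raw += pssm.matrix[i, idx[sym]] if sym in idx else pssm.gap_penalty
    return ConservationScore(
        id=record.id,
        category=category,
        raw=raw,
        per_residue=raw / pssm.n,
        genome_id=record.genome_id,
    )


# ---------------------------------------------------------------------------
# BLOSUM scoring
# ---------------------------------------------------------------------------


class ScoringMatrixB:
    """Realised n x 21 BLOSUM62 scoring matrix for a reference set.

    Row i is the BLOSUM62 row of the i-th reference residue over the 20
    amino acids, extended by a 21st gap column holding ``gap_penalty``.
    """

    SYMBOLS = AMINO_ACIDS + GAP

    def __init__(
        self,
        ref_set: ReferenceResidueSet,
        gap_penalty: float = DEFAULT_GAP_PENALTY,
    ):
        base = substitution_matrices.load("BLOSUM62")
        self.ref_set = ref_set
        self.gap_penalty = float(gap_penalty)
        B = np.empty((ref_set.n, 21))
        for i, (_, res) in enumerate(ref_set.entries):
            for j, a in enumerate(AMINO_ACIDS):
                B[i, j] = float(base[res, a])
            B[i, 20] = self.gap_penalty
        self.B = B

    @property
    def n(self) -> int:
        return self.ref_set.n

    @property
    def n_symbol_states(self) -> int:
        return self.B.shape[1]


def score_blosum(
    B: ScoringMatrixB,
    record: SequenceRecord,
    columns: Sequence[int],
    category: str | None = None,
) -> ConservationScore:
    """Sum BLOSUM62 substitution scores of the row against the reference set."""
    if len(columns) != B.n:
        raise ScoringError(
            f"{len(columns)} columns given for a reference set of size {B.n}"
        )
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    raw = 0.0
    for i, col in enumerate(columns):
        if col < 1 or col > len(record.residues):
            raise ScoringError(f"column {col} out of range for row {record.id!r}")
        sym = record.residues[col - 1]
        raw += B.B[i, idx[sym]] if sym in idx else B.B[i, 20]
    return ConservationScore(
        id=record.id,
        category=category or B.ref_set.category,
        raw=raw,
        per_residue=raw / B.n,
        genome_id=record.genome_id,
    )


# ---------------------------------------------------------------------------
# High-level scoring over an alignment
# ---------------------------------------------------------------------------


def score_alignment(
    alignment: Alignment,
    ref_set: ReferenceResidueSet,
    method: str = "pssm",
    reference_rows: Sequence[str] | None = None,
    beta: float = 1.0,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    include_reference: bool = False,
) -> list[ConservationScore]:
    """Map the reference set onto the alignment and score every row.

    ``reference_rows`` restricts the PSSM construction to the named rows
    (default: the reference sequence itself, the N=1 case).
    """
    columns = map_reference_positions(alignment, ref_set)
    targets = [
        rec
        for rec in alignment
        if include_reference or rec.id != ref_set.reference_id
    ]
    if method == "pssm":
        ref_ids = list(reference_rows) if reference_rows else [ref_set.reference_id]
        pssm = build_pssm(
            [alignment.get(r) for r in ref_ids],
            columns,
            beta=beta,
            gap_penalty=gap_penalty,
        )
        return [score_pssm(pssm, rec, category=ref_set.category) for rec in targets]
    if method == "blosum":
        B = ScoringMatrixB(ref_set, gap_penalty=gap_penalty)
        return [score_blosum(B, rec, columns) for rec in targets]
    raise ScoringError(f"unknown scoring method {method!r}")


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_scores(
    scores: Sequence[ConservationScore],
    method: str = "quartile",
    breaks: Sequence[float] | None = None,
) -> list[ConservationScore]:
    """Assign each score one of four categorical bins.

    ``quartile`` uses the raw-score quartiles of the scored population
    (a score equal to a boundary falls in the lower bin); ``fixed`` takes
    three ascending breakpoints defining the four bins.
    """
    scores = list(scores)
    if method == "quartile":
        if len(scores) < 4:
            raise ScoringError("quartile binning needs at least 4 scores")
        raws = np.array([s.raw for s in scores])
        b = np.quantile(raws, [0.25, 0.5, 0.75])
    elif method == "fixed":
        if breaks is None or len(breaks) != 3:
            raise ScoringError("fixed binning needs exactly 3 breakpoints")
        b = np.asarray(breaks, dtype=float)
        if not (b[0] < b[1] < b[2]):
            raise ScoringError("breakpoints must be strictly ascending")
    else:
        raise ScoringError(f"unknown binning method {method!r}")
    out = []
    for s in scores:
        k = int(np.searchsorted(b, s.raw, side="left"))
        out.append(replace_bin(s, BIN_NAMES[k]))
    return out


def replace_bin(score: ConservationScore, bin_name: str) -> ConservationScore:
    return ConservationScore(
        id=score.id,
        category=score.category,
        raw=score.raw,
        per_residue=score.per_residue,
        bin=bin_name,
        genome_id=score.genome_id,
    )


def merge_low_bins(bin_name: str) -> str:
    """Three-way reading of the four bins (the two low bins merged)."""
    return "low" if bin_name in ("extremely_low", "low") else bin_name


# ---------------------------------------------------------------------------
# Genome-level interface summaries
# ---------------------------------------------------------------------------


@dataclass
class GenomeInterfaceRecord:
    genome_id: str
    ar1_score: float
    det287_score: float
    class_label: str
    best_protein_id: str


@dataclass
class ClassRegression:
    class_label: str
    slope: float
    intercept: float
    pearson_r: float
    n: int


def paired_interface_table(
    hth_scores: Sequence[ConservationScore],
    ctd_scores: Sequence[ConservationScore],
    class_labels: Mapping[str, str],
) -> tuple[list[GenomeInterfaceRecord], dict[str, ClassRegression]]:
    """Join per-protein DNA-binding-domain scores with per-genome interface
    scores and fit a per-class least-squares line (interface on AR1).

    Genomes carrying an interface score but no protein are dropped with a
    warning; an empty join is an error.  Degenerate regressions (constant
    values or fewer than 2 points) report slope 0 and an undefined (NaN)
    correlation with a warning.
    """
    ctd_by_genome = {(s.genome_id or s.id): s for s in ctd_scores}
    records: list[GenomeInterfaceRecord] = []
    seen_genomes: set[str] = set()
    for s in hth_scores:
        g = s.genome_id or s.id
        if g not in ctd_by_genome:
            continue
        seen_genomes.add(g)
        records.append(
            GenomeInterfaceRecord(
                genome_id=g,
                ar1_score=s.raw,
                det287_score=ctd_by_genome[g].raw,
                class_label=class_labels.get(g, "unassigned"),
                best_protein_id=s.id,
            )
        )
    dropped = sorted(set(ctd_by_genome) - seen_genomes)
    if dropped:
        logger.warning(
            "%d genome(s) have an interface score but no protein: %s",
            len(dropped),
            dropped[:5],
        )
    if not records:
        raise ScoringError("empty join between protein and interface scores")

    fits: dict[str, ClassRegression] = {}
    by_class: dict[str, list[GenomeInterfaceRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_label, []).append(r)
    for label, rs in sorted(by_class.items()):
        x = np.array([r.ar1_score for r in rs])
        y = np.array([r.det287_score for r in rs])
        if len(rs) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "class %r: degenerate regression (n=%d); slope 0, r undefined",
                label,
                len(rs),
            )
            fits[label] = ClassRegression(label, 0.0, float(np.mean(y)), math.nan, len(rs))
            continue
        res = stats.linregress(x, y)
        fits[label] = ClassRegression(
            label, float(res.slope), float(res.intercept), float(res.rvalue), len(rs)
        )
    return records, fits


def best_per_genome(
    scores: Sequence[ConservationScore],
) -> list[ConservationScore]:
    """Keep, per genome and category, the maximum raw score.

    Ties break to the smallest protein id; output ordered by (genome,
    category).
    """
    best: dict[tuple[str, str], ConservationScore] = {}
    for s in scores:
        key = (s.genome_id or s.id, s.category)
        cur = best.get(key)
        if cur is None or s.raw > cur.raw or (s.raw == cur.raw and s.id < cur.id):
            best[key] = s
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Per-class residue frequencies (heatmap-style summary, emitted as a table)
# ---------------------------------------------------------------------------


def residue_frequencies(
    alignment: Alignment,
    columns: Sequence[int],
    class_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-class residue frequency at each mapped column (long format)."""
    rows = []
    by_class: dict[str, list[SequenceRecord]] = {}
    for rec in alignment:
        by_class.setdefault(class_labels.get(rec.id, "unassigned"), []).append(rec)
    for label, recs in sorted(by_class.items()):
        for col in columns:
            syms = [r.residues[col - 1] for r in recs]
            total = len(syms)
            for a in AMINO_ACIDS + GAP:
                c = syms.count(a)
                if c:
                    rows.append(
                        {
                            "class": label,
                            "column": col,
                            "residue": a,
                            "frequency": c / total,
                        }
                    )
    return pd.DataFrame(rows, columns=["class", "column", "residue", "frequency"])


# ---------------------------------------------------------------------------
# Score table I/O
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["id", "genome_id", "category", "raw", "per_residue", "bin"]


def write_scores(scores: Iterable[ConservationScore], path) -> None:
    rows = [
        {
            "id": s.id,
            "genome_id": s.genome_id,
            "category": s.category,
            "raw": f"{s.raw:.6f}",
            "per_residue": f"{s.per_residue:.6f}",
            "bin": s.bin or "",
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scores(path) -> list[ConservationScore]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        ConservationScore(
            id=r.id,
            genome_id=r.genome_id,
            category=r.category,
            raw=float(r.raw),
            per_residue=float(r.per_residue),
            bin=r.bin or None,
        )
        for r in df.itertuples()
    ]
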