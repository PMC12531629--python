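"""Readers and writers for the text formats the pipeline touches.

FASTA (via Bio.SeqIO), Newick, IQ-TREE-style ancestral ``.state`` tables,
iTOL annotation datasets, and the tab-separated per-sequence metadata table.
All writers are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .asr import AncestralStates, N_STATES
from .records import (
    AMINO_ACIDS,
    RecordError,
    SequenceRecord,
    check_unique_ids,
)
from .tree import Tree, parse_newick

logger = logging.getLogger(__name__)

STATE_HEADER = ["Node", "Site", "State"] + [f"p_{a}" for a in AMINO_ACIDS]

#: Fixed 4-colour palette for the categorical score bins (low to high).
#: The upstream study does not describe its colour scales; this choice is an
#: arbitrary colour-blind-safe ramp.
BIN_PALETTE = {
    "extremely_low": "#d7191c",
    "low": "#fdae61",
    "medium": "#abd9e9",
    "high": "#2c7bb6",
}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    The header token before the first whitespace becomes the id, sequences
    are uppercased and terminal ``'*'`` stop symbols are stripped.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().strip("*")
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise RecordError(f"no FASTA records in {path}")
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path) -> Tree:
    text = Path(path).read_text()
    return parse_newick(text)


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Metadata table
# ---------------------------------------------------------------------------

META_COLUMNS = ["id", "genome_id", "taxon", "annotations"]


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sequence metadata table (TSV with the standard header)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise RecordError(f"metadata table {path} lacks columns {missing}")
    return df[META_COLUMNS]


def write_metadata(records: Iterable[SequenceRecord], path) -> None:
    rows = [
        {
            "id": rec.id,
            "genome_id": rec.genome_id,
            "taxon": rec.taxon or "",
            "annotations": ",".join(sorted(rec.annotations)),
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def apply_metadata(
    records: Sequence[SequenceRecord], meta: pd.DataFrame
) -> list[SequenceRecord]:
    """Return records with genome/taxon/annotations filled from the table."""
    by_id = meta.set_index("id")
    out = []
    for rec in records:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            ann = frozenset(t for t in str(row["annotations"]).split(",") if t)
            out.append(
                SequenceRecord(
                    id=rec.id,
                    residues=rec.residues,
                    genome_id=str(row["genome_id"]),
                    taxon=str(row["taxon"]) or None,
                    annotations=ann,
                )
            )
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# IQ-TREE-style ancestral state tables
# ---------------------------------------------------------------------------


def read_iqtree_states(path, tree: Tree) -> AncestralStates:
    """Parse an IQ-TREE-style ``.state`` table against a fixed tree.

    Tab-separated columns: Node, Site (1-based), State, then 20 posterior
    probabilities in alphabetical one-letter amino-acid order.  Lines
    starting with ``#`` (and an optional literal header row) are skipped.
    Rows whose probabilities sum outside [0.99, 1.01] are renormalised with
    a logged warning; a state of ``'-'`` marks a gap-flagged column.
    """
    known = {n.name for n in tree.postorder() if not n.is_tip}
    raw: dict[str, dict[int, np.ndarray]] = {}
    gaps: dict[str, set[int]] = {}
    max_site = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "Node" and fields[1] == "Site":
                continue  # header row
            if len(fields) != 3 + N_STATES:
                raise RecordError(
                    f"{path}:{lineno}: expected {3 + N_STATES} fields, "
                    f"got {len(fields)}"
                )
            node, site_s, state = fields[0], fields[1], fields[2]
            if node not in known:
                raise RecordError(
                    f"{path}:{lineno}: node {node!r} not an internal node "
                    "of the tree"
                )
            try:
                site = int(site_s)
                probs = np.array([float(x) for x in fields[3:]])
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if site < 1:
                raise RecordError(f"{path}:{lineno}: sites are 1-based")
            s = probs.sum()
            if not 0.99 <= s <= 1.01:
                logger.warning(
                    "%s:%d: probabilities sum to %.4f; renormalising",
                    path,
                    lineno,
                    s,
                )
            if s <= 0:
                raise RecordError(f"{path}:{lineno}: non-positive probability row")
            probs = probs / s
            raw.setdefault(node, {})[site] = probs
            if state == "-":
                gaps.setdefault(node, set()).add(site)
            max_site = max(max_site, site)

    if not raw:
        raise RecordError(f"no state rows in {path}")
    posteriors: dict[str, np.ndarray] = {}
    gap_flags: dict[str, np.ndarray] = {}
    for node, sites in raw.items():
        if len(sites) != max_site:
            missing = sorted(set(range(1, max_site + 1)) - set(sites))
            raise RecordError(
                f"node {node!r}: missing sites {missing[:5]}... of {max_site}"
            )
        P = np.vstack([sites[s] for s in range(1, max_site + 1)])
        posteriors[node] = P
        g = np.zeros(max_site, dtype=bool)
        for s in gaps.get(node, ()):
            g[s - 1] = True
        gap_flags[node] = g
    order = [n.name for n in tree.postorder() if not n.is_tip and n.name in raw]
    return AncestralStates(order, max_site, posteriors, gap_flags)


def write_iqtree_states(states: AncestralStates, path) -> None:
    """Write ancestral states in the IQ-TREE-style tab-separated dialect."""
    with open(path, "w") as fh:
        fh.write("# marginal ancestral state posteriors\n")
        fh.write("\t".join(STATE_HEADER) + "\n")
        for node in states.node_names:
            P = states.posteriors[node]
            flags = states.gap_flags[node]
            for site in range(1, states.n_cols + 1):
                state = "-" if flags[site - 1] else states.map_residue(node, site)
                probs = "\t".join(f"{p:.8f}" for p in P[site - 1])
                fh.write(f"{node}\t{site}\t{state}\t{probs}\n")


# ---------------------------------------------------------------------------
# iTOL datasets
# ---------------------------------------------------------------------------


def write_itol_dataset(scores, kind: str, path, label: str = "conservation") -> None:
    """Export conservation scores as an iTOL annotation dataset.

    ``kind='colorstrip'`` colours each tree node by its categorical bin
    (requires binned scores); ``kind='gradient'`` emits the numeric raw
    scores.
    """
    scores = list(scores)
    if not scores:
        raise RecordError("empty score list")
    if kind not in ("colorstrip", "gradient"):
        raise RecordError(f"unknown iTOL dataset kind {kind!r}")
    for sc in scores:
        if "\t" in sc.id:
            raise RecordError(f"score id {sc.id!r} contains the separator (tab)")
    lines = []
    if kind == "colorstrip":
        lines += [
            "DATASET_COLORSTRIP",
            "SEPARATOR TAB",
            f"DATASET_LABEL\t{label}",
            "COLOR\t#2c7bb6",
            "LEGEND_TITLE\tscore bin",
            "LEGEND_SHAPES\t" + "\t".join("1" for _ in BIN_PALETTE),
            "LEGEND_COLORS\t" + "\t".join(BIN_PALETTE.values()),
            "LEGEND_LABELS\t" + "\t".join(BIN_PALETTE),
            "DATA",
        ]
        for sc in scores:
            if sc.bin is None:
                raise RecordError(
                    f"score for {sc.id!r} is unbinned; colorstrip needs bins"
                )
            lines.append(f"{sc.id}\t{BIN_PALETTE[sc.bin]}")
    else:
        lines += [
            "DATASET_GRADIENT",
            "SEPARATOR TAB",
            f"DATASET_LABEL\t{label}",
            "COLOR\t#2c7bb6",
            "COLOR_MIN\t#ffffff",
            "COLOR_MAX\t#2c7bb6",
            "DATA",
        ]
        for sc in scores:
            lines.append(f"{sc.id}\t{sc.raw:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
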