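"""Family-class assignment from pairwise-similarity clustering.

Sequences are clustered by single-linkage connected components over relative
global-alignment scores (score(i, j) at least a fraction of the smaller
self-score), then labelled: a cluster containing a designated seed sequence
takes the seed's class (e.g. ``Eco-CRP``); a seedless cluster whose members
carry orthology annotations takes the majority annotation's ``<label>-like``
class; anything else is ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, nw_score, self_score
from .records import SequenceRecord


class ClassifyError(ValueError):
    pass


#: Default mapping from orthology annotation tags to class stems.
DEFAULT_ANNOTATION_LABELS = {"crp": "CRP", "fnr": "FNR"}


@dataclass
class SimilarityMatrix:
    ids: list[str]
    scores: np.ndarray  # symmetric, diagonal = self-score

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ClassifyError("score matrix shape does not match ids")
        if not np.allclose(self.scores, self.scores.T):
            raise ClassifyError("score matrix must be symmetric")

    def self_scores(self) -> np.ndarray:
        return np.diag(self.scores)


@dataclass
class ClassLabel:
    id: str
    label: str
    basis: str  # seed-cluster | annotation-mixture | unassigned


def pairwise_scores(
    seqs: Sequence[SequenceRecord],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SimilarityMatrix:
    """All-vs-all global alignment scores (BLOSUM62, affine gaps).

    The diagonal holds each sequence's self-score (sum of diagonal
    substitution scores), the raw-score analogue of a bitscore ceiling.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ClassifyError("need at least 2 sequences")
    plain = [r.ungapped for r in seqs]
    n = len(seqs)
    S = np.zeros((n, n))
    for i in range(n):
        S[i, i] = self_score(plain[i])
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = nw_score(plain[i], plain[j], gap_open, gap_extend)
    return SimilarityMatrix([r.id for r in seqs], S)


def cluster_by_score(sim: SimilarityMatrix, rel_threshold: float) -> list[list[str]]:
    """Single-linkage components over relative-score edges.

    An edge joins i, j when score(i, j) >= rel_threshold * min(self_i,
    self_j).  Components are returned sorted by their smallest member id,
    members sorted within.
    """
    if not 0.0 < rel_threshold <= 1.0:
        raise ClassifyError("rel_threshold must lie in (0, 1]")
    n = len(sim.ids)
    selfs = sim.self_scores()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim.scores[i, j] >= rel_threshold * min(selfs[i], selfs[j]):
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(sim.ids[i])
    out = [sorted(members) for members in comps.values()]
    return sorted(out, key=lambda c: c[0])


def assign_class_labels(
    clusters: Sequence[Sequence[str]],
    seeds: Mapping[str, str],
    annotations: Mapping[str, frozenset[str] | set[str]] | None = None,
    annotation_labels: Mapping[str, str] | None = None,
) -> list[ClassLabel]:
    """Label every clustered sequence.

    ``seeds`` maps class label -> seed sequence id (e.g. ``{"Eco-CRP":
    "b3357"}``).  A cluster containing a seed takes that label; two seeds
    with different labels in one cluster is an error.  A seedless cluster
    whose members carry annotations takes ``<stem>-like`` for the majority
    annotation (ties to the alphabetically first stem); otherwise members
    are ``unassigned``.
    """
    annotations = annotations or {}
    annotation_labels = annotation_labels or DEFAULT_ANNOTATION_LABELS
    seed_of = {seq_id: label for label, seq_id in seeds.items()}
    all_ids = {m for c in clusters for m in c}
    missing = sorted(set(seed_of) - all_ids)
    if missing:
        raise ClassifyError(f"seed ids not among inputs: {missing}")

    out: list[ClassLabel] = []
    for cluster in clusters:
        labels_here = sorted({seed_of[m] for m in cluster if m in seed_of})
        if len(labels_here) > 1:
            raise ClassifyError(
                f"ambiguous seeding: cluster contains seeds for {labels_here}"
            )
        if labels_here:
            for m in cluster:
                out.append(ClassLabel(m, labels_here[0], "seed-cluster"))
            continue
        tally: dict[str, int] = {}
        for m in cluster:
            for tag in annotations.get(m, ()):  # type: ignore[arg-type]
                if tag in annotation_labels:
                    stem = annotation_labels[tag]
                    tally[stem] = tally.get(stem, 0) + 1
        if tally:
            best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            for m in cluster:
                out.append(ClassLabel(m, f"{best}-like", "annotation-mixture"))
        else:
            for m in cluster:
                out.append(ClassLabel(m, "unassigned", "unassigned"))
    return out
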