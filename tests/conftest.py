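"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hthcons import Alignment, SequenceRecord
from hthcons.records import AMINO_ACIDS
from hthcons.simulate import functional_reference, make_benchmark


@pytest.fixture(scope="session")
def ar1_truth():
    """One seeded ar1_gain benchmark reused by read-only tests."""
    return make_benchmark("ar1_gain", seed=1)


@pytest.fixture(scope="session")
def ar1_scoring_alignment(ar1_truth):
    """Benchmark alignment with the synthetic functional reference appended."""
    return Alignment(list(ar1_truth.alignment) + [functional_reference(ar1_truth)])


def brute_force_column_loglik(tree, tip_states: dict[str, str], model) -> float:
    """Exhaustive enumeration oracle for a single alignment column.

    Sums, over every assignment of the 20 states to the internal nodes, the
    product of the root prior and the per-branch transition probabilities.
    Exponential in the internal node count: only for tiny trees.
    """
    internals = [n for n in tree.postorder() if not n.is_tip]
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    total = 0.0
    for combo in itertools.product(range(20), repeat=len(internals)):
        assign = {n.name: s for n, s in zip(internals, combo)}
        for name, aa in tip_states.items():
            assign[name] = idx[aa]
        p = model.pi[assign[tree.root.name]]
        for node in tree.postorder():
            if node.parent is None:
                continue
            P = model.transition(node.length)
            p *= P[assign[node.parent.name], assign[node.name]]
        total += p
    return float(np.log(total))


def random_records(rng, n, length, prefix="s"):
    return [
        SequenceRecord(
            id=f"{prefix}{i}",
            residues="".join(rng.choice(list(AMINO_ACIDS), size=length)),
        )
        for i in range(n)
    ]
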