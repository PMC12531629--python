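"""I/O round trips and format contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hthcons import SequenceRecord, parse_newick, poisson_model
from hthcons.asr import marginal_asr
from hthcons.conscore import ConservationScore
from hthcons.records import AMINO_ACIDS, RecordError
from hthcons.seqio import (
    apply_metadata,
    read_fasta,
    read_iqtree_states,
    read_metadata,
    read_newick,
    write_fasta,
    write_iqtree_states,
    write_itol_dataset,
    write_metadata,
    write_newick,
)
from hthcons.simulate import simulate_tree, evolve_family, SimConfig
from hthcons.tree import TreeError


# ---------------------------------------------------------------------- FASTA


@pytest.mark.parametrize(
    "text,expected",
    [
        (">s1\nMKR\n", [("s1", "MKR")]),
        (">a desc here\nMK\n>b\nRR\n", [("a", "MK"), ("b", "RR")]),
        (">low\nmkr*\n", [("low", "MKR")]),  # uppercased, stop stripped
    ],
)
def test_read_fasta_basic(tmp_path, text, expected):
    p = tmp_path / "in.fasta"
    p.write_text(text)
    recs = read_fasta(p)
    assert [(r.id, r.residues) for r in recs] == expected


def test_read_fasta_duplicate_id(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">a\nMK\n>a\nRR\n")
    with pytest.raises(RecordError, match="'a'"):
        read_fasta(p)


def test_read_fasta_illegal_symbol_position(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nMK7R\n")
    with pytest.raises(RecordError, match="position 3"):
        read_fasta(p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=150),
        min_size=1,
        max_size=6,
    )
)
def test_fasta_round_trip(tmp_path_factory, seqs):
    recs = [SequenceRecord(id=f"r{i}", residues=s) for i, s in enumerate(seqs)]
    p = tmp_path_factory.mktemp("fa") / "out.fasta"
    write_fasta(recs, p)
    back = read_fasta(p)
    assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


# --------------------------------------------------------------------- Newick


def test_read_newick_lengths(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:2):1,C:3);\n")
    t = read_newick(p)
    assert sorted(t.tip_names()) == ["A", "B", "C"]
    assert t.find("A").length == 1.0
    assert t.find("C").length == 3.0


def test_read_newick_default_lengths():
    t = parse_newick("(A,B);")
    assert all(n.length == 0.0 for n in t.postorder())


def test_read_newick_unbalanced_offset():
    with pytest.raises(TreeError, match="character"):
        parse_newick("((A,B;")


def test_newick_support_values_stored_unused():
    t = parse_newick("((A:1,B:1)95:0.5,C:1);")
    supports = [n.support for n in t.internals() if n.support is not None]
    assert supports == [95.0]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_newick_round_trip(tmp_path, seed):
    t = simulate_tree(12, 1.0, seed)
    p = tmp_path / "t.nwk"
    write_newick(t, p)
    back = read_newick(p)
    assert back.newick() == t.newick()
    for node in t.postorder():
        assert math.isclose(back.find(node.name).length, node.length, abs_tol=1e-9)


# ------------------------------------------------------------- state tables


def make_states(seed=0, n_taxa=6, n_sites=12):
    tree = simulate_tree(n_taxa, 1.0, seed)
    truth = evolve_family(tree, SimConfig(n_taxa=n_taxa, n_sites=n_sites, seed=seed))
    return tree, marginal_asr(tree, truth.alignment, poisson_model())


def test_state_file_round_trip(tmp_path):
    tree, states = make_states()
    p = tmp_path / "states.tsv"
    write_iqtree_states(states, p)
    back = read_iqtree_states(p, tree)
    assert back.node_names == states.node_names
    for node in states.node_names:
        assert back.map_sequence(node) == states.map_sequence(node)
        np.testing.assert_allclose(
            back.posteriors[node], states.posteriors[node], atol=1e-6
        )


def _state_row(node, site, state, probs):
    return f"{node}\t{site}\t{state}\t" + "\t".join(f"{p}" for p in probs)


def test_read_states_argmax_and_tie(tmp_path):
    tree = parse_newick("((A:1,B:1)Node5:1,C:1);")
    probs_r = [0.1 / 19] * 20
    probs_r[AMINO_ACIDS.index("R")] = 0.9
    uniform = [0.05] * 20
    p = tmp_path / "s.tsv"
    p.write_text(
        "# comment\n"
        + _state_row("Node5", 1, "R", probs_r)
        + "\n"
        + _state_row("Node5", 2, "A", uniform)
        + "\n"
        + _state_row("Node1", 1, "R", probs_r)
        + "\n"
        + _state_row("Node1", 2, "A", uniform)
        + "\n"
    )
    st_ = read_iqtree_states(p, tree)
    assert st_.map_residue("Node5", 1) == "R"
    # exact tie on a uniform posterior resolves to the alphabetically first
    assert st_.map_residue("Node5", 2) == "A"


def test_read_states_unknown_node(tmp_path):
    tree = parse_newick("((A:1,B:1):1,C:1);")
    p = tmp_path / "s.tsv"
    p.write_text(_state_row("NodeX", 1, "A", [0.05] * 20) + "\n")
    with pytest.raises(RecordError, match="NodeX"):
        read_iqtree_states(p, tree)


def test_read_states_renormalises_offsum(tmp_path, caplog):
    tree = parse_newick("((A:1,B:1):1,C:1);")
    p = tmp_path / "s.tsv"
    bad = [0.1] * 20  # sums to 2.0
    p.write_text(
        _state_row("Node1", 1, "A", bad) + "\n" + _state_row("Node2", 1, "A", bad) + "\n"
    )
    with caplog.at_level("WARNING"):
        st_ = read_iqtree_states(p, tree)
    assert "renormalis" in caplog.text
    np.testing.assert_allclose(st_.posteriors["Node1"].sum(), 1.0, atol=1e-9)


# ----------------------------------------------------------------- iTOL


def scores(n=2, binned=True):
    return [
        ConservationScore(
            id=f"T{i}", category="AR1", raw=float(i), per_residue=float(i) / 3,
            bin="high" if binned else None,
        )
        for i in range(n)
    ]


def test_itol_colorstrip(tmp_path):
    p = tmp_path / "itol.txt"
    write_itol_dataset(scores(2), "colorstrip", p)
    text = p.read_text()
    assert "DATASET_COLORSTRIP" in text
    assert len([l for l in text.splitlines() if l.startswith("T")]) == 2


def test_itol_gradient_numeric(tmp_path):
    p = tmp_path / "itol.txt"
    write_itol_dataset(scores(3, binned=False), "gradient", p)
    lines = [l for l in p.read_text().splitlines() if l.startswith("T")]
    assert all(float(l.split("\t")[1]) == i for i, l in enumerate(lines))


def test_itol_errors(tmp_path):
    with pytest.raises(RecordError, match="empty"):
        write_itol_dataset([], "colorstrip", tmp_path / "x.txt")
    bad = scores(1)
    bad[0].id = "a\tb"
    with pytest.raises(RecordError, match="separator"):
        write_itol_dataset(bad, "colorstrip", tmp_path / "x.txt")


# ----------------------------------------------------------------- metadata


def test_metadata_round_trip(tmp_path):
    recs = [
        SequenceRecord(
            id="a", residues="MK", genome_id="g1", taxon="gamma",
            annotations=frozenset({"crp", "fnr"}),
        ),
        SequenceRecord(id="b", residues="RR", genome_id="g2"),
    ]
    p = tmp_path / "meta.tsv"
    write_metadata(recs, p)
    plain = [SequenceRecord(id=r.id, residues=r.residues) for r in recs]
    back = apply_metadata(plain, read_metadata(p))
    assert back[0].genome_id == "g1"
    assert back[0].annotations == frozenset({"crp", "fnr"})
    assert back[1].taxon is None
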