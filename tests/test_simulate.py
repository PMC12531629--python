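"""Generator correctness: Yule depths, stationarity, planted conservation."""

import math

import numpy as np
import pytest
from scipy import stats

from hthcons.models import poisson_model
from hthcons.records import AMINO_ACIDS
from hthcons.simulate import (
    SimConfig,
    SimulationError,
    SiteConstraint,
    evolve_family,
    make_benchmark,
    simulate_tree,
)


# ------------------------------------------------------------------ Yule tree


def test_two_taxon_tree_is_rooted():
    t = simulate_tree(2, 1.0, seed=1)
    assert len(t.tips()) == 2
    assert t.rooted and len(t.root.children) == 2


def test_tree_determinism():
    assert simulate_tree(16, 2.0, seed=9).newick() == simulate_tree(16, 2.0, seed=9).newick()
    assert simulate_tree(16, 2.0, seed=9).newick() != simulate_tree(16, 2.0, seed=10).newick()


def test_tree_rejects_degenerate():
    with pytest.raises(SimulationError):
        simulate_tree(1, 1.0, 0)


def test_yule_depth_matches_closed_form():
    """Mean root-to-tip depth ~ sum 1/k, k=2..n (Monte Carlo vs closed form)."""
    n, reps = 64, 200
    expected = sum(1.0 / k for k in range(2, n + 1))
    depths = []
    for seed in range(reps):
        t = simulate_tree(n, 1.0, seed=seed)
        d = t.depths()
        depths.append(np.mean([d[name] for name in t.tip_names()]))
    se = np.std(depths, ddof=1) / math.sqrt(reps)
    assert abs(np.mean(depths) - expected) < 3 * se + 1e-12


# ------------------------------------------------------------ family evolution


def test_zero_branch_scale_freezes_root():
    tree = simulate_tree(8, 1.0, 3)
    truth = evolve_family(tree, SimConfig(n_taxa=8, branch_scale=0.0, n_sites=30, seed=4))
    root_seq = truth.node_sequences[tree.root.name]
    assert all(seq == root_seq for seq in truth.node_sequences.values())


def test_strong_constraint_dominates():
    tree = simulate_tree(16, 1.0, 5)
    cfg = SimConfig(
        n_taxa=16,
        n_sites=20,
        site_constraints=(SiteConstraint(7, "W", 50.0, "root"),),
        seed=6,
    )
    truth = evolve_family(tree, cfg)
    assert all(
        truth.node_sequences[t][6] == "W" for t in truth.true_tree.tip_names()
    )


def test_determinism_byte_identical():
    tree = simulate_tree(10, 1.0, 2)
    cfg = dict(n_taxa=10, n_sites=25, gap_rate=0.1, seed=13)
    a = evolve_family(tree, SimConfig(**cfg))
    b = evolve_family(tree, SimConfig(**cfg))
    assert [r.residues for r in a.alignment] == [r.residues for r in b.alignment]
    assert a.node_sequences == b.node_sequences


def test_boosted_stationary_frequency():
    """Tip frequency of the target at a long-branch constrained site matches
    the boosted stationary distribution (Monte Carlo, 500 replicate sites)."""
    lam = 2.0
    model = poisson_model()
    boosted = model.boosted("W", lam)
    p_target = boosted.pi[AMINO_ACIDS.index("W")]
    # 2 taxa, very long branches: each tip state is an independent draw from
    # the boosted stationary distribution at the constrained site
    hits, n = 0, 0
    for seed in range(250):
        tree = simulate_tree(2, 1.0, seed=seed)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = 50.0
        cfg = SimConfig(
            n_taxa=2,
            n_sites=2,
            site_constraints=(SiteConstraint(1, "W", lam, "root"),),
            seed=seed,
        )
        truth = evolve_family(tree, cfg)
        for t in tree.tip_names():
            hits += truth.node_sequences[t][0] == "W"
            n += 1
    se = math.sqrt(p_target * (1 - p_target) / n)
    assert abs(hits / n - p_target) < 3 * se


def test_stationarity_without_constraints():
    """Long-path tip residues follow the model's stationary frequencies."""
    tree = simulate_tree(2, 1.0, seed=0)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = 100.0
    truth = evolve_family(tree, SimConfig(n_taxa=2, n_sites=5000, seed=1))
    counts = np.zeros(20)
    for t in tree.tip_names():
        for s in truth.node_sequences[t]:
            counts[AMINO_ACIDS.index(s)] += 1
    res = stats.chisquare(counts)
    assert res.pvalue > 0.01


def test_conservation_monotone_in_lambda():
    """Raising the constraint strength never lowers target frequency."""
    freqs = []
    for lam in (0.0, 1.0, 2.0, 4.0):
        hits = n = 0
        for seed in range(40):
            tree = simulate_tree(8, 1.0, seed=seed)
            cfg = SimConfig(
                n_taxa=8,
                n_sites=4,
                site_constraints=(
                    tuple(SiteConstraint(1, "W", lam, "root") for _ in range(1))
                    if lam > 0
                    else ()
                ),
                seed=seed + 1000,
            )
            truth = evolve_family(tree, cfg)
            for t in tree.tip_names():
                hits += truth.node_sequences[t][0] == "W"
                n += 1
        freqs.append(hits / n)
    assert all(b >= a - 0.02 for a, b in zip(freqs, freqs[1:]))


def test_gaps_are_irreversible():
    tree = simulate_tree(12, 1.0, 8)
    truth = evolve_family(tree, SimConfig(n_taxa=12, n_sites=40, gap_rate=0.15, seed=3))
    # a column gapped in an ancestor must be gapped in every descendant tip:
    # check via the alignment — tips within a clade share ancestral gaps
    gap_sets = {r.id: {i for i, s in enumerate(r.residues) if s == "-"} for r in truth.alignment}
    for node in truth.true_tree.postorder():
        if node.is_tip or node.parent is None:
            continue
        tips = truth.true_tree.tips_below(node)
        shared = set.intersection(*(gap_sets[t] for t in tips))
        for t in tips:
            assert shared <= gap_sets[t]


# ------------------------------------------------------------------ benchmarks


def test_ar1_gain_labels_match_designated_clade(ar1_truth):
    planted = {t for t, l in ar1_truth.clade_labels.items() if l == "planted"}
    stems = {
        c.active_clade
        for c in ar1_truth.config.site_constraints
        if c.active_clade != "root"
    }
    assert len(stems) == 1
    stem = ar1_truth.true_tree.find(stems.pop())
    assert planted == set(ar1_truth.true_tree.tips_below(stem))
    # designated clade holds roughly a quarter of the tips
    assert 0.1 <= len(planted) / 64 <= 0.45


def test_base_contacts_global_dominant_lambda():
    truth = make_benchmark("base_contacts_global", seed=2, lam=50.0)
    sites = [(p, r) for p, r in truth.refsets["specific_base"].entries]
    for t in truth.true_tree.tip_names():
        seq = truth.node_sequences[t]
        assert all(seq[p - 1] == r for p, r in sites)


def test_backbone_patchy_deactivated_clades():
    truth = make_benchmark("backbone_patchy", seed=4, lam=50.0)
    c = truth.config.site_constraints[0]
    assert len(c.inactive_clades) >= 1
    assert c.lam == 25.0  # half strength


def test_unknown_preset():
    with pytest.raises(SimulationError, match="preset"):
        make_benchmark("nonsense", seed=0)
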