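"""Reference mapping, PSSM/BLOSUM scoring, binning and genome summaries."""

import math

import numpy as np
import pytest

from hthcons.conscore import (
    ConservationScore,
    ReferenceResidueSet,
    ScoringError,
    ScoringMatrixB,
    best_per_genome,
    bin_scores,
    build_pssm,
    ecocrp_reference,
    load_table1,
    map_reference_positions,
    merge_low_bins,
    paired_interface_table,
    read_reference_sets,
    residue_frequencies,
    score_blosum,
    score_pssm,
    write_reference_sets,
)
from hthcons.records import AMINO_ACIDS, Alignment, SequenceRecord


def aln(**rows):
    return Alignment(SequenceRecord(id=k, residues=v) for k, v in rows.items())


def refset(category="custom", ref="ref", entries=((1, "R"),)):
    return ReferenceResidueSet(category=category, reference_id=ref, entries=entries)


# ------------------------------------------------------------- reference sets


def test_refset_invariants():
    with pytest.raises(ScoringError, match="increasing"):
        refset(entries=((5, "R"), (3, "K")))
    with pytest.raises(ScoringError, match="invalid residue"):
        refset(entries=((1, "Z"),))
    with pytest.raises(ScoringError, match="nonempty"):
        refset(entries=())


def test_packaged_reference_sets():
    t1 = load_table1()
    assert t1["AR1"].n == 11
    assert t1["phosphate_backbone"].n == 7
    assert t1["specific_base"].n == 3
    assert t1["AR1"].residues == "PDAMTHPDGMQ"
    assert "ten" in t1["AR1"].notes  # tabulated/prose count discrepancy kept


def test_reference_row_reads_back_key_residues():
    """Mapping positions onto an alignment of the packaged reference and
    reading the row back returns exactly the tabulated residues."""
    ref = ecocrp_reference()
    alignment = Alignment([ref, SequenceRecord(id="other", residues=ref.residues)])
    for rs in load_table1().values():
        cols = map_reference_positions(alignment, rs)
        row = alignment.get(rs.reference_id).residues
        assert "".join(row[c - 1] for c in cols) == rs.residues


def test_reference_set_tsv_round_trip(tmp_path):
    sets = load_table1()
    p = tmp_path / "refsets.tsv"
    write_reference_sets(sets, p)
    back = read_reference_sets(p)
    assert {k: v.entries for k, v in back.items()} == {
        k: v.entries for k, v in sets.items()
    }


# ------------------------------------------------------------ column mapping


def test_map_positions_counts_gaps():
    a = aln(ref="MK-RE-R", x="MKARENR")
    rs = refset(ref="ref", entries=((3, "R"), (5, "R")))
    assert map_reference_positions(a, rs) == [4, 7]


def test_map_positions_identity_when_ungapped():
    ref = ecocrp_reference()
    a = Alignment([ref])
    rs = load_table1()["specific_base"]
    assert map_reference_positions(a, rs) == [180, 181, 185]


def test_map_positions_errors():
    a = aln(ref="MKR", x="MKR")
    with pytest.raises(ScoringError, match="absent"):
        map_reference_positions(a, refset(ref="nope"))
    with pytest.raises(ScoringError, match="beyond"):
        map_reference_positions(a, refset(ref="ref", entries=((9, "R"),)))


def test_map_positions_warns_on_mismatch(caplog):
    a = aln(ref="MKW")
    with caplog.at_level("WARNING"):
        cols = map_reference_positions(a, refset(ref="ref", entries=((3, "R"),)))
    assert cols == [3] and "expected" in caplog.text


# ----------------------------------------------------------------------- PSSM


def test_pssm_single_reference_entries():
    p = build_pssm(["R"], [1])
    iR = AMINO_ACIDS.index("R")
    assert p.matrix[0, iR] == pytest.approx(math.log2(0.525 / 0.05))
    assert p.matrix[0, 0] == pytest.approx(-1.0)  # unobserved residue


def test_pssm_prior_washout():
    p = build_pssm(["R"], [1], beta=1e9)
    assert np.all(np.abs(p.matrix) < 1e-6)


def test_pssm_all_gap_column_error():
    with pytest.raises(ScoringError, match="gapped"):
        build_pssm(["-"], [1])


def test_score_pssm_matching_sequence():
    p = build_pssm(["RKW"], [1, 2, 3])
    s = score_pssm(p, SequenceRecord(id="x", residues="RKW"))
    assert s.raw == pytest.approx(3 * math.log2(10.5))
    assert s.per_residue == pytest.approx(s.raw / 3)


def test_score_pssm_all_gaps():
    p = build_pssm(["RKW"], [1, 2, 3])
    s = score_pssm(p, SequenceRecord(id="x", residues="---"))
    assert s.raw == pytest.approx(-0.36)


def test_reference_optimality():
    """With N=1 the reference attains the maximal achievable raw score, and
    restoring any key residue never lowers either scheme's score."""
    rng = np.random.default_rng(5)
    ref_seq = "".join(rng.choice(list(AMINO_ACIDS), size=10))
    cols = [2, 5, 9]
    p = build_pssm([ref_seq], cols)
    rs = ReferenceResidueSet(
        category="custom",
        reference_id="ref",
        entries=tuple((c, ref_seq[c - 1]) for c in cols),
    )
    B = ScoringMatrixB(rs)
    ref_rec = SequenceRecord(id="ref", residues=ref_seq)
    best_pssm = score_pssm(p, ref_rec).raw
    best_blosum = score_blosum(B, ref_rec, cols).raw
    for _ in range(50):
        other = "".join(rng.choice(list(AMINO_ACIDS), size=10))
        rec = SequenceRecord(id="o", residues=other)
        assert score_pssm(p, rec).raw <= best_pssm + 1e-12
        # substituting the reference residue back never decreases the score
        for c in cols:
            fixed = other[: c - 1] + ref_seq[c - 1] + other[c:]
            frec = SequenceRecord(id="f", residues=fixed)
            assert score_pssm(p, frec).raw >= score_pssm(p, rec).raw - 1e-12
            assert (
                score_blosum(B, frec, cols).raw
                >= score_blosum(B, rec, cols).raw - 1e-12
            )


def test_score_additivity_across_categories():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=20))
    rec = SequenceRecord(id="x", residues=seq)
    ref = "".join(rng.choice(list(AMINO_ACIDS), size=20))
    cols_a, cols_b = [1, 4], [7, 11, 15]
    pa, pb = build_pssm([ref], cols_a), build_pssm([ref], cols_b)
    pab = build_pssm([ref], cols_a + cols_b)
    assert score_pssm(pab, rec).raw == pytest.approx(
        score_pssm(pa, rec).raw + score_pssm(pb, rec).raw
    )


# --------------------------------------------------------------------- BLOSUM


def test_b_matrix_has_21_states():
    rs = refset(entries=((1, "R"), (2, "E"), (3, "R")))
    B = ScoringMatrixB(rs)
    assert B.B.shape == (3, 21)
    assert B.n_symbol_states == 21
    assert np.all(B.B[:, 20] == -0.12)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("RER", 15.0),  # diagonal R=5, E=5, R=5
        ("REK", 12.0),  # R<->K substitution scores 2
        ("RE-", 9.88),  # gap state: 5 + 5 - 0.12
        ("REX", 9.88),  # 'X' scored as gap
    ],
)
def test_blosum_scoring_examples(seq, expected):
    rs = refset(entries=((1, "R"), (2, "E"), (3, "R")))
    B = ScoringMatrixB(rs)
    s = score_blosum(B, SequenceRecord(id="x", residues=seq), [1, 2, 3])
    assert s.raw == pytest.approx(expected)


# -------------------------------------------------------------------- binning


def sc(raw, i=0, genome="g", cat="AR1"):
    return ConservationScore(
        id=f"p{i}", category=cat, raw=raw, per_residue=raw, genome_id=genome
    )


def test_quartile_binning_one_per_bin():
    out = bin_scores([sc(1.0, 0), sc(2.0, 1), sc(3.0, 2), sc(4.0, 3)], "quartile")
    assert [s.bin for s in out] == ["extremely_low", "low", "medium", "high"]


def test_fixed_binning():
    out = bin_scores([sc(7.0)], "fixed", breaks=(0, 5, 10))
    assert out[0].bin == "medium"
    with pytest.raises(ScoringError, match="ascending"):
        bin_scores([sc(1.0)], "fixed", breaks=(5, 5, 10))


def test_merged_low_bins_three_way():
    assert merge_low_bins("extremely_low") == merge_low_bins("low") == "low"
    assert merge_low_bins("high") == "high"


# ------------------------------------------------------- genome-level summary


def test_paired_table_perfect_line():
    hth = [sc(float(i), i, genome=f"g{i}") for i in range(5)]
    ctd = [
        ConservationScore(
            id=f"g{i}", category="det287", raw=2.0 * i + 1.0, per_residue=0.0,
            genome_id=f"g{i}",
        )
        for i in range(5)
    ]
    records, fits = paired_interface_table(hth, ctd, {f"g{i}": "Eco-CRP" for i in range(5)})
    assert len(records) == 5
    fit = fits["Eco-CRP"]
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.slope == pytest.approx(2.0, abs=1e-9)
    assert fit.intercept == pytest.approx(1.0, abs=1e-9)


def test_paired_table_degenerate_constant(caplog):
    hth = [sc(float(i), i, genome=f"g{i}") for i in range(4)]
    ctd = [
        ConservationScore(id=f"g{i}", category="det287", raw=3.0, per_residue=0.0)
        for i in range(4)
    ]
    with caplog.at_level("WARNING"):
        _, fits = paired_interface_table(hth, ctd, {})
    fit = fits["unassigned"]
    assert fit.slope == 0.0 and math.isnan(fit.pearson_r)
    assert "degenerate" in caplog.text


def test_paired_table_empty_join():
    with pytest.raises(ScoringError, match="empty join"):
        paired_interface_table([sc(1.0, genome="a")], [
            ConservationScore(id="b", category="det287", raw=1.0, per_residue=1.0)
        ], {})


def test_best_per_genome():
    scores = [
        sc(3.1, 0, genome="g1"),
        sc(7.2, 1, genome="g1"),
        sc(5.0, 2, genome="g2"),
        sc(5.0, 3, genome="g2"),  # tie: p2 < p3 keeps p2
    ]
    best = best_per_genome(scores)
    by_genome = {s.genome_id: s for s in best}
    assert by_genome["g1"].raw == 7.2
    assert by_genome["g2"].id == "p2"
    assert len(best) == 2  # one entry per (genome, category)


def test_residue_frequencies_sum_to_one():
    a = aln(x="RK", y="RW", z="KK")
    df = residue_frequencies(a, [1, 2], {"x": "c1", "y": "c1", "z": "c2"})
    sums = df.groupby(["class", "column"])["frequency"].sum()
    assert np.allclose(sums, 1.0)
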