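"""Translated matching: six-frame translation, Smith-Waterman vs independent
oracles, Karlin-Altschul E-values, EST-protein matching and deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import Seq

import concord
from concord import seqmatch
from concord.config import SimConfig
from concord.errors import InputError
from oracles import blosum, exhaustive_local_score, gotoh_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------------------ protein DB

def test_build_protein_db_counts_and_errors():
    db = seqmatch.build_protein_db([
        ("p1", "", "A" * 100), ("p2", "", "C" * 200), ("p3", "", "D" * 300)])
    assert db.total_residues == 600 and len(db) == 3
    with pytest.raises(InputError, match="p1"):
        seqmatch.build_protein_db([("p1", "", "AA"), ("p1", "", "CC")])
    with pytest.raises(InputError):
        seqmatch.build_protein_db([])
    with pytest.warns(UserWarning, match="illegal"):
        db2 = seqmatch.build_protein_db([("ok", "", "ACDEFGHIK"),
                                         ("bad", "", "ACDEF123")])
    assert list(db2.entries) == ["ok"]


def test_db_from_de_protein_fixture_scale():
    """A DB built from 42 distinct protein stand-ins indexes 42 entries."""
    cfg = SimConfig(n_genes=42, seed=6)
    truth = concord.generate_ground_truth(cfg)
    db = seqmatch.build_protein_db(
        (a, "", s) for a, s in zip(truth.table.protein_acc,
                                   truth.table.protein_seq))
    assert len(db) == 42


# ------------------------------------------------------------ translation

def test_six_frame_translation_examples():
    fr = seqmatch.translate_six_frames("ATGGCC")
    assert fr[1] == "MA"
    assert fr[-1] == "GH"  # revcomp GGCCAT -> GH
    fr7 = seqmatch.translate_six_frames("ATGGCCA")
    assert len(fr7[2]) == 2 and len(fr7[3]) == 1
    assert seqmatch.translate_six_frames("TAATAG")[1] == "**"
    assert seqmatch.translate_six_frames("ATNGCC")[1][0] == "X"
    with pytest.raises(InputError):
        seqmatch.translate_six_frames("AT")


def test_translation_consistency_with_biopython_on_random_seqs():
    rng = np.random.default_rng(2)
    for _ in range(10):
        nt = "".join(rng.choice(list("ACGT"), 60))
        fr = seqmatch.translate_six_frames(nt)
        assert fr[1] == str(Seq(nt).translate())
        assert fr[-1] == str(Seq(nt).reverse_complement().translate())


# ------------------------------------------------------------ alignment

def test_identity_score_is_blosum_diagonal_sum():
    pep = "MKTAYIAKQR"
    score, (qs, qe), (ts, te) = seqmatch.local_align(pep, pep)
    assert score == sum(blosum(a, a) for a in pep)
    assert (qs, qe) == (0, 10) and (ts, te) == (0, 10)


def test_reverse_has_no_long_alignment():
    pep = "MKTAYIWCQR"
    score = seqmatch.local_align_score(pep, pep[::-1])
    assert score <= max(blosum(a, a) for a in pep) + 1


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(AA, min_size=1, max_size=12), st.text(AA, min_size=1, max_size=12))
def test_local_align_equals_gotoh_oracle(q, t):
    assert seqmatch.local_align_score(q, t) == gotoh_local_score(q, t)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(AA, min_size=1, max_size=7), st.text(AA, min_size=1, max_size=7))
def test_gotoh_oracle_equals_exhaustive_enumeration(q, t):
    assert gotoh_local_score(q, t) == exhaustive_local_score(q, t)


# ------------------------------------------------------------ E-values

def test_evalue_closed_form_and_linearity():
    e = seqmatch.evalue(50, 100, 1000)
    assert e == pytest.approx(0.041 * 1e5 * np.exp(-0.267 * 50), rel=1e-12)
    assert e == pytest.approx(6.5e-3, rel=0.02)
    assert seqmatch.evalue(500, 100, 1000) < 1e-40
    assert seqmatch.evalue(50, 100, 2000) == pytest.approx(2 * e)
    s1, s2 = seqmatch.bit_score(50), seqmatch.bit_score(60)
    assert s2 > s1


# ------------------------------------------------------------ matching

@pytest.fixture(scope="module")
def small_db():
    cfg = SimConfig(n_genes=20, seed=12)
    truth = concord.generate_ground_truth(cfg)
    db = seqmatch.build_protein_db(
        (a, "", s) for a, s in zip(truth.table.protein_acc,
                                   truth.table.protein_seq))
    return truth, db


def test_match_exact_backtranslation_positive_control(small_db):
    truth, db = small_db
    ests = list(zip(truth.table.gene_id[:5], truth.table.coding_seq[:5]))
    hits = seqmatch.match_ests(ests, db)
    assert len(hits) == 5
    assert (hits.frame == 1).all()
    assert (hits.evalue < 1e-8).all() and hits.annotation_grade.all()
    assert all(p == "P" + e[1:] for e, p in zip(hits.est_id, hits.protein_acc))


def test_match_random_negative_controls(small_db):
    _, db = small_db
    rng = np.random.default_rng(17)
    ests = [(f"R{i:03d}", "".join(rng.choice(list("ACGT"), 150)))
            for i in range(100)]
    hits = seqmatch.match_ests(ests, db)
    assert len(hits) <= 1  # >= 99% of random ESTs find no hit at 1e-5


def test_match_threshold_nesting(small_db):
    truth, db = small_db
    rng = np.random.default_rng(3)
    ests = list(zip(truth.table.gene_id, truth.table.coding_seq))
    ests += [(f"R{i}", "".join(rng.choice(list("ACGT"), 120)))
             for i in range(10)]
    sets = {}
    for e in (1e-8, 1e-5, 1e-3):
        hits = seqmatch.match_ests(ests, db, e_blast=e)
        sets[e] = set(hits.est_id)
    assert sets[1e-8] <= sets[1e-5] <= sets[1e-3]
    hits5 = seqmatch.match_ests(ests, db, e_blast=1e-5)
    assert set(hits5.loc[hits5.annotation_grade, "est_id"]) <= sets[1e-5]


def test_strand_symmetry(small_db):
    """Reverse-complementing an EST moves the hit from frame +k to -k with
    identical score and E-value."""
    truth, db = small_db
    for gid, nt in zip(truth.table.gene_id[:4], truth.table.coding_seq[:4]):
        fwd = seqmatch.match_ests([(gid, nt)], db)
        rc = str(Seq(nt).reverse_complement())
        rev = seqmatch.match_ests([(gid, rc)], db)
        assert len(fwd) == len(rev) == 1
        assert rev.frame.iloc[0] == -fwd.frame.iloc[0]
        assert rev.score.iloc[0] == fwd.score.iloc[0]
        assert rev.evalue.iloc[0] == pytest.approx(fwd.evalue.iloc[0])


# ------------------------------------------------------------ dedup

def _hits(rows):
    cols = ["est_id", "protein_acc", "frame", "score", "bitscore", "evalue",
            "q_start", "q_end", "t_start", "t_end", "annotation_grade"]
    return pd.DataFrame([{**dict.fromkeys(cols, 0), "frame": 1,
                          "annotation_grade": True, **r} for r in rows],
                        columns=cols)


def test_dedup_similar_expression_keeps_largest(small_db):
    hits = _hits([{"est_id": "E1", "protein_acc": "P1"},
                  {"est_id": "E2", "protein_acc": "P1"}])
    fc = pd.DataFrame({"fc_skf": [1.6, 1.8], "fc_ly": [np.nan, np.nan]},
                      index=["E1", "E2"])
    out = seqmatch.dedup_pairs(hits, fc)
    assert list(out.est_id) == ["E2"] and not out.starred.any()


def test_dedup_conflicting_expression_keeps_both_starred():
    # opposite SKF/LY signs on two ESTs of one protein: both kept, starred
    hits = _hits([{"est_id": "E1", "protein_acc": "P1"},
                  {"est_id": "E2", "protein_acc": "P1"},
                  {"est_id": "E3", "protein_acc": "P2"}])
    fc = pd.DataFrame({"fc_skf": [-1.5, 1.4, 2.0],
                       "fc_ly": [np.nan, np.nan, np.nan]},
                      index=["E1", "E2", "E3"])
    out = seqmatch.dedup_pairs(hits, fc)
    assert len(out) == 3
    starred = out.set_index("est_id").starred
    assert starred["E1"] and starred["E2"] and not starred["E3"]


def test_dedup_cross_treatment_profiles_kept_starred():
    """ESTs regulated under different treatments have different expression
    profiles and are both kept (the table's asterisked duplicate rows),
    even when their signs happen to agree."""
    hits = _hits([{"est_id": "E1", "protein_acc": "P1"},
                  {"est_id": "E2", "protein_acc": "P1"}])
    fabp = pd.DataFrame({"fc_skf": [-1.5, np.nan], "fc_ly": [np.nan, 1.4]},
                        index=["E1", "E2"])
    out = seqmatch.dedup_pairs(hits, fabp)
    assert len(out) == 2 and out.starred.all()
    stathmin = pd.DataFrame({"fc_skf": [np.nan, 1.5], "fc_ly": [1.4, np.nan]},
                            index=["E1", "E2"])
    out2 = seqmatch.dedup_pairs(hits, stathmin)
    assert len(out2) == 2 and out2.starred.all()


def test_dedup_single_est_passthrough():
    hits = _hits([{"est_id": "E1", "protein_acc": "P1"}])
    fc = pd.DataFrame({"fc_skf": [1.2], "fc_ly": [np.nan]}, index=["E1"])
    out = seqmatch.dedup_pairs(hits, fc)
    assert len(out) == 1 and not out.starred.iloc[0]
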