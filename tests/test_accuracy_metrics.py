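"""Pairwise alignment, error decomposition, and reference-based MSA scores."""

import random
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asrbench import (
    AMINO_ACIDS,
    InputError,
    PairwiseAlignmentParams,
    cline_shift,
    homology_pairs,
    pairwise_align,
    reconstruction_accuracy,
    score_msa,
    sp_modeler_tc,
)
from asrbench.accuracy_metrics import _scoring_matrix, alignment_score

PARAMS = PairwiseAlignmentParams()

protein = st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=12)


def brute_force_score(a, b, open_=11.0, ext=1.0):
    """Independent exhaustive recursion over alignment paths (affine costs)."""
    mat = _scoring_matrix("BLOSUM62")
    idx = {c: i for i, c in enumerate(AMINO_ACIDS)}

    @lru_cache(maxsize=None)
    def f(i, j, prev):  # prev: 0 diagonal, 1 gap-in-b, 2 gap-in-a
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, mat[idx[a[i]], idx[b[j]]] + f(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, -(ext if prev == 1 else open_) + f(i + 1, j, 1))
        if j < len(b):
            best = max(best, -(ext if prev == 2 else open_) + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


# -- pairwise alignment ----------------------------------------------------


def test_identical_sequences_align_without_gaps():
    a, b = pairwise_align("ACDEFG", "ACDEFG", PARAMS)
    assert a == b == "ACDEFG"


def test_empty_versus_sequence_is_all_gaps():
    a, b = pairwise_align("", "ACDE", PARAMS)
    assert a == "----" and b == "ACDE"
    assert pairwise_align("", "", PARAMS) == ("", "")


def test_alignment_score_matches_exhaustive_recursion():
    rng = random.Random(7)
    for _ in range(25):
        a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 8)))
        b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 8)))
        assert alignment_score(a, b, PARAMS) == pytest.approx(brute_force_score(a, b))


def test_emitted_alignment_scores_its_reported_optimum():
    """Traceback self-consistency: re-scoring the emitted rows equals the DP score."""
    mat = _scoring_matrix("BLOSUM62")
    idx = {c: i for i, c in enumerate(AMINO_ACIDS)}
    rng = random.Random(11)
    for _ in range(15):
        a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 10)))
        b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 10)))
        ra, rb = pairwise_align(a, b, PARAMS)
        score = 0.0
        run_a = run_b = 0
        for x, y in zip(ra, rb):
            if x != "-" and y != "-":
                score += mat[idx[x], idx[y]]
                run_a = run_b = 0
            elif y == "-":
                score -= PARAMS.gap_extend if run_a else PARAMS.gap_open
                run_a, run_b = run_a + 1, 0
            else:
                score -= PARAMS.gap_extend if run_b else PARAMS.gap_open
                run_b, run_a = run_b + 1, 0
        assert score == pytest.approx(alignment_score(a, b, PARAMS))


def test_deterministic_alignment():
    assert pairwise_align("ACDEF", "ACEF", PARAMS) == pairwise_align("ACDEF", "ACEF", PARAMS)


def test_non_amino_characters_rejected():
    with pytest.raises(InputError):
        pairwise_align("AC1E", "ACDE", PARAMS)


# -- error decomposition ---------------------------------------------------


def test_perfect_match_scores_one():
    rec = reconstruction_accuracy("ACDEFGHIK", "ACDEFGHIK")
    assert rec.accuracy == 1.0
    assert rec.insertion_error == rec.deletion_error == rec.substitution_error == 0.0


def test_empty_reconstruction_is_pure_deletion_error():
    rec = reconstruction_accuracy("", "ACDE")
    assert rec.deletion_error == 1.0
    assert rec.accuracy == 0.0


def test_single_substitution_in_four_columns():
    rec = reconstruction_accuracy("ACFE", "ACDE")
    assert rec.substitution_error == 0.25
    assert rec.accuracy == 0.75
    assert rec.alignment_length == 4


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=protein, b=protein)
def test_decomposition_identity_and_symmetry(a, b):
    rec = reconstruction_accuracy(a, b)
    total = (rec.insertion_error + rec.deletion_error
             + rec.substitution_error + rec.accuracy)
    assert total == pytest.approx(1.0, abs=1e-12)
    for v in (rec.insertion_error, rec.deletion_error, rec.substitution_error, rec.accuracy):
        assert 0.0 <= v <= 1.0
    swapped = reconstruction_accuracy(b, a)
    assert swapped.insertion_error == pytest.approx(rec.deletion_error, abs=1e-12)
    assert swapped.deletion_error == pytest.approx(rec.insertion_error, abs=1e-12)
    assert swapped.substitution_error == pytest.approx(rec.substitution_error, abs=1e-12)
    assert swapped.accuracy == pytest.approx(rec.accuracy, abs=1e-12)


# -- MSA quality scores ----------------------------------------------------

REF = {"s1": "AC-E", "s2": "ACDE", "s3": "A-DE"}


def oracle_scores(test, ref):
    """Double-loop enumeration of residue pairs and columns."""

    def cols(msa):
        labels = sorted(msa)
        counters = {k: 0 for k in labels}
        out = []
        for c in range(len(msa[labels[0]])):
            col = []
            for k in labels:
                if msa[k][c] != "-":
                    col.append((k, counters[k]))
                    counters[k] += 1
            out.append(col)
        return out

    def pairs(msa):
        ps = set()
        for col in cols(msa):
            for i in range(len(col)):
                for j in range(i + 1, len(col)):
                    ps.add((col[i], col[j]))
        return ps

    tp, rp = pairs(test), pairs(ref)
    shared = len(tp & rp)
    sp = shared / len(rp) if rp else 0.0
    modeler = shared / len(tp) if tp else 0.0
    rc = [frozenset(c) for c in cols(ref) if c]
    tcset = {frozenset(c) for c in cols(test) if c}
    tc = sum(1 for c in rc if c in tcset) / len(rc) if rc else 0.0
    return sp, modeler, tc


def test_reference_against_itself_is_perfect():
    assert sp_modeler_tc(REF, REF) == (1.0, 1.0, 1.0)
    assert cline_shift(REF, REF) == pytest.approx(1.0)
    s = score_msa(REF, REF)
    assert (s.sp_score, s.modeler_score, s.tc_score, s.cline_shift) == (1, 1, 1, 1)


def test_fully_disjoint_test_alignment_scores_zero():
    ref = {"s1": "AC", "s2": "WD"}
    test = {"s1": "AC--", "s2": "--WD"}
    sp, modeler, tc = sp_modeler_tc(test, ref)
    assert sp == 0.0 and tc == 0.0 and modeler == 0.0  # 0/0 defined as 0


def test_three_sequence_toy_matches_pair_enumeration_oracle():
    test = {"s1": "ACE-", "s2": "ACDE", "s3": "AD-E"}
    assert sp_modeler_tc(test, REF) == pytest.approx(oracle_scores(test, REF))


def test_homology_invariant_to_column_permutation_and_scores_to_row_order():
    """The homology-pair set of a gap-free MSA ignores column order, and the
    scores ignore row order."""
    rng = random.Random(3)
    aln = {f"s{i}": "".join(rng.choice(AMINO_ACIDS) for _ in range(6)) for i in range(3)}
    cols = list(range(6))
    rng.shuffle(cols)
    permuted = {k: "".join(v[c] for c in cols) for k, v in aln.items()}
    assert homology_pairs(permuted) == homology_pairs(aln)
    test = {"s1": "ACE-", "s2": "ACDE", "s3": "AD-E"}
    reordered = dict(reversed(list(test.items())))
    assert sp_modeler_tc(reordered, REF) == sp_modeler_tc(test, REF)
    assert cline_shift(reordered, REF) == pytest.approx(cline_shift(test, REF))


def test_tc_bounded_by_sp_when_columns_are_split():
    """Splitting reference columns (underalignment) keeps residue order, and
    with uniformly occupied reference columns a reproduced column implies all
    its pairs reproduced, so TC <= SP."""
    rng = random.Random(5)
    for _ in range(20):
        L = rng.randint(2, 8)
        ref = {f"s{i}": "".join(rng.choice(AMINO_ACIDS) for _ in range(L)) for i in range(3)}
        labels = sorted(ref)
        test = {k: "" for k in ref}
        for c in range(L):
            if rng.random() < 0.4:  # split this column: each row in its own column
                for i, k in enumerate(labels):
                    for j, kk in enumerate(labels):
                        test[kk] += ref[k][c] if i == j else "-"
            else:
                for k in labels:
                    test[k] += ref[k][c]
        sp, modeler, tc = sp_modeler_tc(test, ref)
        assert tc <= sp + 1e-12
        assert sp <= 1.0 and modeler <= 1.0


def test_row_set_mismatch_rejected():
    with pytest.raises(InputError):
        sp_modeler_tc({"s1": "AC"}, {"s2": "AC"})
    with pytest.raises(InputError):
        sp_modeler_tc({"s1": "AC"}, {"s1": "AD"})


def test_cline_shift_two_sequence_hand_computation():
    ref = {"a": "ARND-", "b": "-RNDC"}
    test = {"a": "ARND--", "b": "--RNDC"}
    eps = 0.2
    # hand enumeration: ref aligns a-residues 1,2,3 (R,N,D) to b 0,1,2;
    # test aligns a 2,3 to b 0,1 and nothing else.
    # direction test->ref: pairs (a2,b0): ref partner of a2 is b1 -> shift 1;
    # (a3,b1): ref partner b2 -> shift 1. each term (1.2/2 - 0.2) = 0.4
    # direction ref->test: (a1,b0): test partner of a1 absent -> 0;
    # (a2,b1): test partner b0 -> shift 1 -> 0.4; (a3,b2): test b1 -> 0.4
    expected = (0.4 + 0.4 + 0.0 + 0.4 + 0.4) / (2 + 3)
    assert cline_shift(test, ref, eps) == pytest.approx(expected, abs=1e-12)


def test_far_shift_scores_nonpositive():
    ref = {"a": "AAAAAAAAAA" + "-" * 10, "b": "AAAAAAAAAA" + "-" * 10}
    # align a's residues to b's with a 10-residue offset
    test = {"a": "AAAAAAAAAA" + "-" * 10, "b": "-" * 10 + "AAAAAAAAAA"}
    ref = {"a": ref["a"], "b": "AAAAAAAAAA" + "-" * 10}
    score = cline_shift(test, ref, 0.2)
    assert score <= 0.0
    assert score >= -0.2


def test_homology_pairs_counts():
    pairs = homology_pairs(REF)
    # columns: {s1:0,s2:0,s3:0}, {s1:1,s2:1}, {s2:2,s3:1}, {s1:2,s2:3,s3:2}
    assert len(pairs) == 3 + 1 + 1 + 3
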