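"""Reconstruction accuracy and alignment quality scoring.

Reconstruction accuracy follows an error decomposition over the columns of a
deterministic global pairwise alignment between the reconstructed and the
true ancestral sequence: insertion error (residue in the reconstruction,
gap in the truth), deletion error (gap in the reconstruction, residue in the
truth) and substitution error (mismatched residues), each divided by the
alignment length; accuracy is one minus their sum, i.e. the fraction of
columns carrying a correctly aligned, correct residue.

MSA quality is scored against the true alignment with the four classic
reference-based measures: Developer/SP score, Modeler score, Total Column
score, and the Cline shift score (epsilon = 0.2, symmetrized over both
directions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .errors import InputError
from .protein_sim import AMINO_ACIDS, GAP

__all__ = [
    "PairwiseAlignmentParams",
    "AccuracyRecord",
    "MsaQualityScores",
    "pairwise_align",
    "reconstruction_accuracy",
    "homology_pairs",
    "sp_modeler_tc",
    "cline_shift",
    "score_msa",
]

_AA_SET = set(AMINO_ACIDS)


@dataclass(frozen=True)
class PairwiseAlignmentParams:
    """Deterministic affine-gap global alignment settings.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Traceback
    ties are broken with the fixed high-road preference match > delete >
    insert, so the alignment is a pure function of its inputs.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    tie_break: str = "high_road"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties must be >= 0")


@lru_cache(maxsize=4)
def _scoring_matrix(name: str) -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    out = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


_NEG = -1e30


def _affine_dp(S: np.ndarray, open_: float, ext: float) -> Tuple[float, List[Tuple[int, int]]]:
    """Gotoh DP over a precomputed (n, m) column-score matrix.

    Returns the optimal score and the aligned index pairs, where -1 marks a
    gap.  States: M (both advance), X (gap in the second input: 'delete'),
    Y (gap in the first: 'insert'); ties resolve M > X > Y.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -open_ - ext * np.arange(n)
    if m:
        Y[0, 1:] = -open_ - ext * np.arange(m)
    jj = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevX), prevY)
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum(np.maximum(prevM[1:], prevY[1:]) - open_, prevX[1:] - ext)
        # Y has an in-row recurrence; solve it with a cumulative-max transform
        cand = np.full(m + 1, _NEG)
        cand[1:] = np.maximum(M[i, :-1], X[i, :-1]) - open_ + ext * jj[1:]
        run = np.maximum.accumulate(cand)
        Y[i, 1:] = np.maximum(run[1:] - ext * jj[1:], Y[i, 1:])
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback, recomputing the decisions with fixed preference M > X > Y
    pairs: List[Tuple[int, int]] = []
    i, j = n, m
    state = ("M", "X", "Y")[int(np.argmax([M[n, m], X[n, m], Y[n, m]]))]
    while i > 0 or j > 0:
        if j == 0:
            state = "X"
        elif i == 0:
            state = "Y"
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = ("M", "X", "Y")[int(np.argmax(prev))]
            i, j = i - 1, j - 1
        elif state == "X":
            prev = (M[i - 1, j] - open_, X[i - 1, j] - ext, Y[i - 1, j] - open_)
            pairs.append((i - 1, -1))
            state = ("M", "X", "Y")[int(np.argmax(prev))]
            i -= 1
        else:
            prev = (M[i, j - 1] - open_, X[i, j - 1] - open_, Y[i, j - 1] - ext)
            pairs.append((-1, j - 1))
            state = ("M", "X", "Y")[int(np.argmax(prev))]
            j -= 1
    pairs.reverse()
    return float(score), pairs


def _validate_protein(seq: str) -> None:
    bad = set(seq) - _AA_SET
    if bad:
        raise InputError(f"non-amino-acid characters in sequence: {sorted(bad)}")


def pairwise_align(
    seq_a: str, seq_b: str, params: PairwiseAlignmentParams = PairwiseAlignmentParams()
) -> Tuple[str, str]:
    """Global affine-gap alignment of two protein sequences (two gapped rows)."""
    _validate_protein(seq_a)
    _validate_protein(seq_b)
    if not seq_a and not seq_b:
        return "", ""
    if not seq_a:
        return GAP * len(seq_b), seq_b
    if not seq_b:
        return seq_a, GAP * len(seq_a)
    mat = _scoring_matrix(params.matrix)
    ia = [AMINO_ACIDS.index(c) for c in seq_a]
    ib = [AMINO_ACIDS.index(c) for c in seq_b]
    S = mat[np.ix_(ia, ib)]
    _, pairs = _affine_dp(S, params.gap_open, params.gap_extend)
    row_a = "".join(seq_a[i] if i >= 0 else GAP for i, _ in pairs)
    row_b = "".join(seq_b[j] if j >= 0 else GAP for _, j in pairs)
    return row_a, row_b


def alignment_score(
    seq_a: str, seq_b: str, params: PairwiseAlignmentParams = PairwiseAlignmentParams()
) -> float:
    """Score of the optimal global affine-gap alignment."""
    _validate_protein(seq_a)
    _validate_protein(seq_b)
    if not seq_a or not seq_b:
        L = max(len(seq_a), len(seq_b))
        return 0.0 if L == 0 else -(params.gap_open + params.gap_extend * (L - 1))
    mat = _scoring_matrix(params.matrix)
    S = mat[np.ix_([AMINO_ACIDS.index(c) for c in seq_a],
                   [AMINO_ACIDS.index(c) for c in seq_b])]
    score, _ = _affine_dp(S, params.gap_open, params.gap_extend)
    return score


@dataclass(frozen=True)
class AccuracyRecord:
    """Error decomposition for one reconstructed ancestor.

    The four proportions are fractions of pairwise-alignment columns and sum
    to 1 with the accuracy.
    """

    node_label: str
    distance_to_root: float
    insertion_error: float
    deletion_error: float
    substitution_error: float
    accuracy: float
    alignment_length: int


def reconstruction_accuracy(
    recon_seq: str,
    true_seq: str,
    node_label: str = "",
    distance_to_root: float = float("nan"),
    params: PairwiseAlignmentParams = PairwiseAlignmentParams(),
) -> AccuracyRecord:
    """Score a reconstructed ancestor against the true ancestral sequence."""
    row_r, row_t = pairwise_align(recon_seq, true_seq, params)
    L = len(row_r)
    if L == 0:
        return AccuracyRecord(node_label, distance_to_root, 0.0, 0.0, 0.0, 1.0, 0)
    ins = dele = sub = match = 0
    for a, b in zip(row_r, row_t):
        if a != GAP and b == GAP:
            ins += 1
        elif a == GAP and b != GAP:
            dele += 1
        elif a == b:
            match += 1
        else:
            sub += 1
    return AccuracyRecord(
        node_label=node_label,
        distance_to_root=distance_to_root,
        insertion_error=ins / L,
        deletion_error=dele / L,
        substitution_error=sub / L,
        accuracy=match / L,
        alignment_length=L,
    )


# -- MSA quality against a reference --------------------------------------


def _check_same_content(test: Mapping[str, str], ref: Mapping[str, str]) -> None:
    if set(test) != set(ref):
        raise InputError(
            f"row sets differ: only-test={sorted(set(test) - set(ref))}, "
            f"only-ref={sorted(set(ref) - set(test))}"
        )
    for k in test:
        if test[k].replace(GAP, "") != ref[k].replace(GAP, ""):
            raise InputError(f"degapped sequence mismatch for row {k!r}")


def _residue_index_columns(msa: Mapping[str, str]) -> List[Set[Tuple[str, int]]]:
    """Each column as the set of (row label, residue index) it aligns."""
    labels = list(msa)
    lengths = {len(v) for v in msa.values()}
    if len(lengths) != 1:
        raise InputError("alignment rows have unequal lengths")
    counters = {k: 0 for k in labels}
    cols = []
    for c in range(lengths.pop()):
        col = set()
        for k in labels:
            if msa[k][c] != GAP:
                col.add((k, counters[k]))
                counters[k] += 1
        cols.append(col)
    return cols


def homology_pairs(msa: Mapping[str, str]) -> Set[Tuple[Tuple[str, int], Tuple[str, int]]]:
    """All aligned residue pairs ((row, idx), (row, idx)), rows in sorted order."""
    pairs = set()
    for col in _residue_index_columns(msa):
        items = sorted(col)
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                pairs.add((items[i], items[j]))
    return pairs


@dataclass(frozen=True)
class MsaQualityScores:
    sp_score: float
    modeler_score: float
    tc_score: float
    cline_shift: float


def sp_modeler_tc(
    test_msa: Mapping[str, str], ref_msa: Mapping[str, str]
) -> Tuple[float, float, float]:
    """Developer/SP, Modeler and Total Column scores of test vs reference.

    SP = shared pairs / reference pairs; Modeler = shared pairs / test pairs
    (0 when the test alignment aligns nothing); TC = fraction of reference
    columns reproduced identically as residue-index sets.
    """
    _check_same_content(test_msa, ref_msa)
    tp = homology_pairs(test_msa)
    rp = homology_pairs(ref_msa)
    shared = len(tp & rp)
    sp = shared / len(rp) if rp else 0.0
    modeler = shared / len(tp) if tp else 0.0
    ref_cols = [c for c in _residue_index_columns(ref_msa) if c]
    test_cols = {frozenset(c) for c in _residue_index_columns(test_msa) if c}
    tc = (
        sum(1 for c in ref_cols if frozenset(c) in test_cols) / len(ref_cols)
        if ref_cols
        else 0.0
    )
    return sp, modeler, tc


def _partner_maps(msa: Mapping[str, str]) -> Dict[Tuple[str, str], Dict[int, int]]:
    """For each ordered row pair (u, v): residue index in u -> partner index in v."""
    maps: Dict[Tuple[str, str], Dict[int, int]] = {}
    labels = sorted(msa)
    cols = _residue_index_columns(msa)
    for u in labels:
        for v in labels:
            if u != v:
                maps[(u, v)] = {}
    for col in cols:
        items = sorted(col)
        for a in range(len(items)):
            for b in range(len(items)):
                if a != b:
                    (u, i), (v, j) = items[a], items[b]
                    maps[(u, v)][i] = j
    return maps


def cline_shift(
    test_msa: Mapping[str, str], ref_msa: Mapping[str, str], epsilon: float = 0.2
) -> float:
    """Symmetrized Cline shift score with parameter epsilon.

    Each residue pair aligned in one alignment is scored
    (1 + eps) / (1 + |shift|) - eps against the partner's position in the
    other alignment (0 if unaligned there); both directions are summed and
    normalized by the total pair count, giving a score in [-eps, 1].
    """
    _check_same_content(test_msa, ref_msa)
    tmap = _partner_maps(test_msa)
    rmap = _partner_maps(ref_msa)
    labels = sorted(test_msa)

    def directional(src, dst):
        num = 0.0
        count = 0
        for a in range(len(labels)):
            for b in range(len(labels)):
                if a >= b:
                    continue
                u, v = labels[a], labels[b]
                for i, j in src[(u, v)].items():
                    count += 1
                    jj = dst[(u, v)].get(i)
                    if jj is not None:
                        num += (1.0 + epsilon) / (1.0 + abs(j - jj)) - epsilon
        return num, count

    n1, c1 = directional(tmap, rmap)
    n2, c2 = directional(rmap, tmap)
    total = c1 + c2
    return (n1 + n2) / total if total else 0.0


def score_msa(
    test_msa: Mapping[str, str], ref_msa: Mapping[str, str], epsilon: float = 0.2
) -> MsaQualityScores:
    """All four quality scores of a test alignment against the reference."""
    sp, modeler, tc = sp_modeler_tc(test_msa, ref_msa)
    return MsaQualityScores(sp, modeler, tc, cline_shift(test_msa, ref_msa, epsilon))
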