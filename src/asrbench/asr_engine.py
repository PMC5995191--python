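"""Marginal maximum-likelihood ancestral sequence reconstruction.

Given a fixed tree with branch lengths, a fixed substitution model and an
alignment of the tips, the engine computes for every internal node and every
alignment column (i) the marginal posterior over the 20 amino acids by the
pruning algorithm with discrete-gamma mixing, and (ii) the posterior
probability that the node has a residue (rather than a gap) at that column,
from a two-state reversible presence/absence model pruned over the same tree.
The reconstructed ancestral sequence reports the most probable residue at
every column whose presence probability reaches the cutoff (default 0.50,
inclusive).

No parameters are estimated: tree, branch lengths and model are taken as
given, mirroring reconstruction on the true tree with the true model.
Gamma categories are mixed by their per-column posterior weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError, InputError
from .phylo_sim import Phylogeny
from .protein_sim import AMINO_ACIDS, GAP, RateModel

__all__ = [
    "MarginalPosterior",
    "ReconstructionResult",
    "column_marginals",
    "presence_marginals",
    "reconstruct",
    "column_log_likelihood",
    "read_fasta_alignment",
]

# characters treated as missing data in the amino-acid model
_MISSING = set("XBZJ?*." + GAP)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
# column reordering so that np.argmax breaks exact ties alphabetically
_ALPHA_ORDER = sorted(range(20), key=lambda i: AMINO_ACIDS[i])


def read_fasta_alignment(text: str) -> Dict[str, str]:
    """Parse FASTA text into an ordered {label: row} mapping."""
    from Bio import SeqIO
    import io

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(text), "fasta")}
    if not rows:
        raise InputError("no FASTA records found")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise InputError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    return rows


@dataclass
class MarginalPosterior:
    """Per-internal-node, per-column marginal posteriors.

    ``amino_acid`` has shape (n_internal, n_columns, 20) and each slice sums
    to 1 over the last axis; ``presence`` has shape (n_internal, n_columns)
    with the posterior probability of a residue (state 1).  Either part may
    be absent depending on which computation produced the object.
    """

    node_labels: List[str]
    amino_acid: Optional[np.ndarray] = None
    presence: Optional[np.ndarray] = None

    def node_index(self, label: str) -> int:
        return self.node_labels.index(label)


@dataclass
class ReconstructionResult:
    """Reconstructed ancestors plus the calls they are built from."""

    sequences: Dict[str, str]            # internal node label -> ungapped sequence
    states: Dict[str, str]               # per-column chosen state, '-' where absent
    presence_calls: Dict[str, np.ndarray]
    cutoff: float
    model_description: str

    def __post_init__(self):
        if not (0 < self.cutoff < 1):
            raise ConfigurationError(f"cutoff must be in (0, 1), got {self.cutoff!r}")


# -- tree indexing ---------------------------------------------------------


class _TreeIndex:
    """Flat postorder arrays for the pruning recursions."""

    def __init__(self, phylo: Phylogeny):
        nodes = list(phylo.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.labels = [Phylogeny.node_label(n) for n in nodes]
        self.is_leaf = [n.is_leaf() for n in nodes]
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        self.branch_lengths = [
            0.0 if n.parent_node is None else float(n.edge.length) for n in nodes
        ]
        self.root = len(nodes) - 1
        self.internal = [i for i in range(len(nodes)) if not self.is_leaf[i]]
        # internal nodes in preorder (matching simulator labeling)
        preorder_internal = [Phylogeny.node_label(n) for n in phylo.preorder() if not n.is_leaf()]
        self.internal_labels = preorder_internal


def _tip_likelihoods(alignment: Mapping[str, str], tree_idx: _TreeIndex,
                     n_states: int, encoder) -> Dict[int, np.ndarray]:
    """Per-tip (n_columns, n_states) conditional likelihood arrays."""
    tips = {tree_idx.labels[i] for i in range(len(tree_idx.labels)) if tree_idx.is_leaf[i]}
    missing = tips - set(alignment)
    if missing:
        raise InputError(f"alignment lacks rows for tips: {sorted(missing)}")
    out = {}
    for i, lab in enumerate(tree_idx.labels):
        if tree_idx.is_leaf[i]:
            out[i] = encoder(alignment[lab])
    return out


def _encode_amino(row: str) -> np.ndarray:
    L = len(row)
    arr = np.zeros((L, 20))
    for j, ch in enumerate(row):
        if ch in _MISSING:
            arr[j, :] = 1.0
        else:
            k = _AA_INDEX.get(ch)
            if k is None:
                raise InputError(f"unknown amino-acid character {ch!r}")
            arr[j, k] = 1.0
    return arr


def _encode_presence(row: str) -> np.ndarray:
    arr = np.zeros((len(row), 2))
    for j, ch in enumerate(row):
        arr[j, 1 if ch != GAP else 0] = 1.0
    return arr


# -- generic pruning -------------------------------------------------------


def _prune(
    tipdata: Dict[int, np.ndarray],
    tree_idx: _TreeIndex,
    P: Dict[Tuple[int, int], np.ndarray],  # (node, category) -> transition matrix
    prior: np.ndarray,
    n_cats: int,
    cat_prior: np.ndarray,
):
    """Inside/outside pruning with per-column scaling.

    Returns (mixed posterior per internal node, per-column total
    log-likelihood, per-column category posterior weights).
    """
    n_nodes = len(tree_idx.labels)
    L = next(iter(tipdata.values())).shape[0]
    S = prior.shape[0]

    inside = [[None] * n_nodes for _ in range(n_cats)]
    logscale = [[None] * n_nodes for _ in range(n_cats)]
    lifted = [[None] * n_nodes for _ in range(n_cats)]  # inside[c] @ P_c.T per node

    for r in range(n_cats):
        for i in range(n_nodes):
            if tree_idx.is_leaf[i]:
                inside[r][i] = tipdata[i]
                logscale[r][i] = np.zeros(L)
            else:
                prod = np.ones((L, S))
                sc = np.zeros(L)
                for c in tree_idx.children[i]:
                    lifted[r][c] = inside[r][c] @ P[(c, r)].T
                    prod = prod * lifted[r][c]
                    sc = sc + logscale[r][c]
                norm = prod.max(axis=1)
                norm = np.where(norm > 0, norm, 1.0)
                inside[r][i] = prod / norm[:, None]
                logscale[r][i] = sc + np.log(norm)

    root = tree_idx.root
    col_loglik_cat = np.empty((n_cats, L))
    for r in range(n_cats):
        lik = inside[r][root] @ prior
        if np.any(lik <= 0):
            raise InputError("zero likelihood column encountered")
        col_loglik_cat[r] = np.log(lik) + logscale[r][root]

    with np.errstate(over="ignore"):
        logw = col_loglik_cat + np.log(cat_prior)[:, None]
        m = logw.max(axis=0)
        w = np.exp(logw - m)
        w /= w.sum(axis=0)
    col_loglik = m + np.log(np.exp(logw - m).sum(axis=0))

    # outside pass (unscaled up to per-column constants, which normalization kills)
    outside = [[None] * n_nodes for _ in range(n_cats)]
    for r in range(n_cats):
        outside[r][root] = np.broadcast_to(prior, (L, S)).copy()
        for i in reversed(range(n_nodes)):  # root first (postorder reversed = preorder-ish)
            if tree_idx.is_leaf[i]:
                continue
            for c in tree_idx.children[i]:
                sib = np.ones((L, S))
                for s in tree_idx.children[i]:
                    if s != c:
                        sib = sib * lifted[r][s]
                pre = outside[r][i] * sib
                o = pre @ P[(c, r)]
                norm = o.max(axis=1)
                norm = np.where(norm > 0, norm, 1.0)
                outside[r][c] = o / norm[:, None]

    # mixed posteriors for internal nodes, ordered per internal_labels (preorder)
    label_to_idx = {tree_idx.labels[i]: i for i in tree_idx.internal}
    post = np.empty((len(tree_idx.internal_labels), L, S))
    for k, lab in enumerate(tree_idx.internal_labels):
        i = label_to_idx[lab]
        acc = np.zeros((L, S))
        for r in range(n_cats):
            joint = inside[r][i] * outside[r][i]
            tot = joint.sum(axis=1, keepdims=True)
            acc += w[r][:, None] * (joint / tot)
        post[k] = acc
    return post, col_loglik, w


def _amino_transition_matrices(tree_idx: _TreeIndex, model: RateModel):
    P = {}
    cache = {}
    for i in range(len(tree_idx.labels)):
        if i == tree_idx.root:
            continue
        t = tree_idx.branch_lengths[i]
        for r, rate in enumerate(model.category_rates):
            key = (t, r)
            if key not in cache:
                cache[key] = expm(model.Q * (t * rate))
            P[(i, r)] = cache[key]
    return P


def column_marginals(
    alignment: Mapping[str, str], tree: Phylogeny, model: RateModel
) -> MarginalPosterior:
    """Amino-acid marginal posteriors at every internal node and column.

    Gaps and ambiguity codes are missing data (likelihood one for every
    state); the root prior is the model's stationary distribution; gamma
    categories are mixed by their per-column posterior weights.
    """
    idx = _TreeIndex(tree)
    tipdata = _tip_likelihoods(alignment, idx, 20, _encode_amino)
    P = _amino_transition_matrices(idx, model)
    K = model.n_categories
    post, _, _ = _prune(tipdata, idx, P, model.frequencies, K, np.full(K, 1.0 / K))
    return MarginalPosterior(node_labels=list(idx.internal_labels), amino_acid=post)


def presence_marginals(
    alignment: Mapping[str, str], tree: Phylogeny, flip_rate: float = 0.1
) -> MarginalPosterior:
    """Posterior probability that each internal node is non-gap at each column.

    Columns are recoded as binary (residue=1, gap=0; ambiguity codes count
    as residues) and pruned under a symmetric two-state model in which the
    expected number of presence flips per unit branch length is
    ``flip_rate`` (by default 0.1, i.e. insertion plus deletion rates of
    0.05 each).
    """
    if not flip_rate > 0:
        raise ConfigurationError(f"flip_rate must be > 0, got {flip_rate!r}")
    idx = _TreeIndex(tree)
    tipdata = _tip_likelihoods(alignment, idx, 2, _encode_presence)
    P = {}
    cache = {}
    for i in range(len(idx.labels)):
        if i == idx.root:
            continue
        t = idx.branch_lengths[i]
        if t not in cache:
            e = np.exp(-2.0 * flip_rate * t)
            cache[t] = np.array([[0.5 + 0.5 * e, 0.5 - 0.5 * e],
                                 [0.5 - 0.5 * e, 0.5 + 0.5 * e]])
        P[(i, 0)] = cache[t]
    prior = np.array([0.5, 0.5])
    post, _, _ = _prune(tipdata, idx, P, prior, 1, np.array([1.0]))
    return MarginalPosterior(node_labels=list(idx.internal_labels), presence=post[:, :, 1])


def column_log_likelihood(
    alignment: Mapping[str, str], tree: Phylogeny, model: RateModel
) -> np.ndarray:
    """Per-column log-likelihood of the alignment (gamma-mixed)."""
    idx = _TreeIndex(tree)
    tipdata = _tip_likelihoods(alignment, idx, 20, _encode_amino)
    P = _amino_transition_matrices(idx, model)
    K = model.n_categories
    _, col_loglik, _ = _prune(tipdata, idx, P, model.frequencies, K, np.full(K, 1.0 / K))
    return col_loglik


def reconstruct(
    alignment: Mapping[str, str],
    tree: Phylogeny,
    model: RateModel,
    cutoff: float = 0.50,
    indel_flip_rate: float = 0.1,
) -> ReconstructionResult:
    """Reconstruct every ancestral sequence from the alignment.

    A column is called present at a node iff its presence posterior is >=
    ``cutoff`` (inclusive); present columns report the argmax of the
    amino-acid posterior, with exact ties broken alphabetically.
    """
    if not (0 < cutoff < 1):
        raise ConfigurationError(f"cutoff must be in (0, 1), got {cutoff!r}")
    aa = column_marginals(alignment, tree, model)
    pres = presence_marginals(alignment, tree, flip_rate=indel_flip_rate)
    sequences: Dict[str, str] = {}
    states: Dict[str, str] = {}
    calls: Dict[str, np.ndarray] = {}
    post = aa.amino_acid[:, :, _ALPHA_ORDER]
    for k, lab in enumerate(aa.node_labels):
        best = np.argmax(post[k], axis=1)
        letters = np.array([AMINO_ACIDS[_ALPHA_ORDER[b]] for b in best])
        present = pres.presence[k] >= cutoff
        row = np.where(present, letters, GAP)
        states[lab] = "".join(row)
        sequences[lab] = "".join(letters[present])
        calls[lab] = present
    return ReconstructionResult(
        sequences=sequences,
        states=states,
        presence_calls=calls,
        cutoff=cutoff,
        model_description=(
            f"WAG+G(alpha={model.gamma_shape},K={model.n_categories}), "
            f"presence flip rate {indel_flip_rate}"
        ),
    )
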