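"""Indel-aware protein sequence evolution along a phylogeny.

Sequences evolve by a continuous-time process with WAG substitutions under
discrete-gamma among-site rate variation, plus insertions and deletions whose
lengths follow a truncated Zipf (power-law) distribution.  Evolution is
simulated event by event (Gillespie) so the full event history is known; the
true multiple alignment of ALL nodes (tips and ancestors) falls out of the
recorded homology columns, which is the point of simulating this way.

Rate conventions: the substitution process is normalized to one expected
substitution per site per unit branch length at stationarity for an
average-rate site.  Insertion and deletion rates are expressed in the same
unit: an insertion rate of 0.05 means 0.05 insertion events per inter-site
slot per unit branch length (slots include both sequence ends, so a sequence
of length L has L + 1 of them); a deletion rate of 0.05 means 0.05 deletion
events per site per unit branch length, independent of the site's gamma
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._wag_data import PAML_ORDER, WAG_EXCHANGEABILITIES_LOWER, WAG_FREQUENCIES
from .errors import ConfigurationError, SimulationError
from .phylo_sim import Phylogeny

__all__ = [
    "AMINO_ACIDS",
    "RateModel",
    "IndelParams",
    "EvolutionHistory",
    "discretize_gamma",
    "draw_indel_length",
    "draw_indel_lengths",
    "evolve",
    "tip_fasta",
    "true_alignment_fasta",
    "ancestors_fasta",
    "wag_matrix",
]

AMINO_ACIDS = PAML_ORDER  # 'ARNDCQEGHILKMFPSTWYV'
GAP = "-"


def wag_matrix() -> Tuple[np.ndarray, np.ndarray]:
    """Return (symmetric 20x20 exchangeability matrix, stationary frequencies)."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(19):          # column-major lower triangle
        for j in range(i + 1, 20):
            s[i, j] = s[j, i] = WAG_EXCHANGEABILITIES_LOWER[k]
            k += 1
    return s, np.array(WAG_FREQUENCIES)


def discretize_gamma(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (mean-of-bin).

    The gamma has shape ``alpha`` and mean 1; each of the ``n_categories``
    equal-probability bins is represented by its conditional mean, so the
    category rates are increasing and average exactly 1.
    """
    if not alpha > 0:
        raise ConfigurationError(f"gamma shape alpha must be > 0, got {alpha!r}")
    if not (isinstance(n_categories, (int, np.integer)) and n_categories >= 1):
        raise ConfigurationError(f"n_categories must be an integer >= 1, got {n_categories!r}")
    K = int(n_categories)
    if K == 1:
        return np.array([1.0])
    # bin boundaries at quantiles i/K of Gamma(alpha, rate alpha)
    bounds = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    # E[X 1{X < t}] for Gamma(shape a, rate a) with mean 1 is gammainc(a + 1, a t)
    partial = gammainc(alpha + 1.0, edges)
    rates = K * np.diff(partial)
    return rates


class RateModel:
    """WAG + discrete-gamma substitution model.

    The generator ``Q`` is normalized so the expected number of substitutions
    per site per unit branch length is 1 at stationarity for a rate-1 site.
    """

    def __init__(
        self,
        exchangeabilities: Optional[np.ndarray] = None,
        stationary_frequencies: Optional[np.ndarray] = None,
        gamma_shape: float = 1.8,
        n_categories: int = 4,
    ):
        if exchangeabilities is None or stationary_frequencies is None:
            s, pi = wag_matrix()
            exchangeabilities = s if exchangeabilities is None else exchangeabilities
            stationary_frequencies = pi if stationary_frequencies is None else stationary_frequencies
        self.exchangeabilities = np.asarray(exchangeabilities, dtype=float)
        self.frequencies = np.asarray(stationary_frequencies, dtype=float)
        if self.exchangeabilities.shape != (20, 20):
            raise ConfigurationError("exchangeabilities must be a 20x20 matrix")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ConfigurationError("exchangeabilities must be symmetric")
        if np.any(self.exchangeabilities < 0) or np.any(self.frequencies < 0):
            raise ConfigurationError("exchangeabilities and frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ConfigurationError("stationary_frequencies must sum to 1")
        self.gamma_shape = float(gamma_shape)
        self.n_categories = int(n_categories)
        self.category_rates = discretize_gamma(self.gamma_shape, self.n_categories)

        Q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.frequencies * np.diag(Q)).sum()
        self.Q = Q / mu
        self.leave_rates = -np.diag(self.Q)  # rate of leaving each residue, per unit rate-1 time
        # jump distribution: P(b | leave a) = Q[a, b] / -Q[a, a]
        jump = self.Q / self.leave_rates[:, None]
        np.fill_diagonal(jump, 0.0)
        self._jump_cum = np.cumsum(jump, axis=1)


@dataclass(frozen=True)
class IndelParams:
    """Insertion/deletion process parameters.

    Rates are per slot (insertion) / per site (deletion) relative to an
    average substitution rate of 1.  Lengths are truncated-Zipf distributed:
    P(L = k) proportional to k^(-zipf_exponent) for 1 <= k <= max_length.
    """

    insertion_rate: float = 0.05
    deletion_rate: float = 0.05
    zipf_exponent: float = 1.7
    max_length: int = 20

    def validate(self) -> None:
        if self.insertion_rate < 0:
            raise ConfigurationError(f"insertion_rate must be >= 0, got {self.insertion_rate!r}")
        if self.deletion_rate < 0:
            raise ConfigurationError(f"deletion_rate must be >= 0, got {self.deletion_rate!r}")
        if not self.zipf_exponent > 1:
            raise ConfigurationError(f"zipf_exponent must be > 1, got {self.zipf_exponent!r}")
        if not (isinstance(self.max_length, (int, np.integer)) and self.max_length >= 1):
            raise ConfigurationError(f"max_length must be an integer >= 1, got {self.max_length!r}")

    def length_pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_length + 1, dtype=float)
        w = k ** (-self.zipf_exponent)
        return w / w.sum()


def draw_indel_length(params: IndelParams, rng: np.random.Generator) -> int:
    """Draw one indel length from the truncated Zipf distribution."""
    return int(draw_indel_lengths(params, rng, 1)[0])


def draw_indel_lengths(params: IndelParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` indel lengths from the truncated Zipf distribution."""
    params.validate()
    cum = np.cumsum(params.length_pmf())
    return np.searchsorted(cum, rng.random(n)) + 1


class _Column:
    """A homology column in the global alignment, a doubly-linked-list node."""

    __slots__ = ("prev", "next", "cat")

    def __init__(self, cat: int):
        self.prev: Optional["_Column"] = None
        self.next: Optional["_Column"] = None
        self.cat = cat


@dataclass
class EvolutionHistory:
    """The simulated truth for one replicate.

    ``sequences`` maps every node label (tips and ancestors) to its ungapped
    amino-acid sequence; ``true_alignment`` maps the same labels to gapped
    rows over the homology columns; ``site_categories`` gives the gamma
    category index of each alignment column; ``event_log`` records every
    indel/substitution event as (branch child label, kind, position, length).
    """

    tree: Phylogeny
    sequences: Dict[str, str]
    true_alignment: Dict[str, str]
    site_categories: List[int]
    event_log: List[Tuple[str, str, int, int]]
    n_rejected: int = 0
    row_order: List[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.site_categories)


def _insert_columns_after(anchor: Optional[_Column], before: Optional[_Column],
                          cats: Sequence[int]) -> List[_Column]:
    """Splice new columns after ``anchor`` (or before ``before`` if anchor is None)."""
    cols = [_Column(c) for c in cats]
    for a, b in zip(cols, cols[1:]):
        a.next, b.prev = b, a
    if anchor is not None:
        right = anchor.next
        anchor.next = cols[0]
        cols[0].prev = anchor
        cols[-1].next = right
        if right is not None:
            right.prev = cols[-1]
    else:
        left = before.prev if before is not None else None
        cols[-1].next = before
        if before is not None:
            before.prev = cols[-1]
        cols[0].prev = left
        if left is not None:
            left.next = cols[0]
    return cols


def _evolve_branch(
    sites: List[List],
    branch_label: str,
    t_total: float,
    model: RateModel,
    indels: IndelParams,
    length_cum: np.ndarray,
    rng: np.random.Generator,
    event_log: List[Tuple[str, str, int, int]],
    head: List[Optional[_Column]],
) -> None:
    """Gillespie simulation along one branch, mutating ``sites`` in place.

    Substitution events are drawn by thinning against the uniform bound
    (max category rate) x (max leave rate), which keeps each step O(1).
    """
    rates = model.category_rates
    leave = model.leave_rates
    jump_cum = model._jump_cum
    freq_cum = np.cumsum(model.frequencies)
    K = model.n_categories
    bound_site = rates.max() * leave.max()

    t = 0.0
    while True:
        L = len(sites)
        if L == 0:
            raise SimulationError(f"sequence went extinct on branch to {branch_label}")
        r_sub = L * bound_site
        r_ins = indels.insertion_rate * (L + 1)
        r_del = indels.deletion_rate * L
        total = r_sub + r_ins + r_del
        t += rng.exponential(1.0 / total)
        if t >= t_total:
            return
        u = rng.random() * total
        if u < r_sub:
            i = int(rng.integers(L))
            col, res = sites[i]
            if rng.random() * bound_site < rates[col.cat] * leave[res]:
                new = int(np.searchsorted(jump_cum[res], rng.random()))
                sites[i][1] = new
                event_log.append((branch_label, "substitution", i, 1))
        elif u < r_sub + r_ins:
            slot = int(rng.integers(L + 1))
            ln = int(np.searchsorted(length_cum, rng.random()) + 1)
            cats = rng.integers(K, size=ln)
            residues = np.searchsorted(freq_cum, rng.random(ln))
            anchor = sites[slot - 1][0] if slot > 0 else None
            before = sites[slot][0] if slot < L else None
            if anchor is None and before is None:  # cannot happen: L >= 1
                raise SimulationError("insertion into empty sequence")
            cols = _insert_columns_after(anchor, before, [int(c) for c in cats])
            if anchor is None and cols[0].prev is None:
                head[0] = cols[0]
            sites[slot:slot] = [[c, int(r)] for c, r in zip(cols, residues)]
            event_log.append((branch_label, "insertion", slot, ln))
        else:
            pos = int(rng.integers(L))
            ln = int(np.searchsorted(length_cum, rng.random()) + 1)
            actual = min(ln, L - pos)
            del sites[pos:pos + actual]
            event_log.append((branch_label, "deletion", pos, actual))


def _evolve_once(
    tree: Phylogeny,
    model: RateModel,
    indels: IndelParams,
    root_length: int,
    rng: np.random.Generator,
) -> EvolutionHistory:
    K = model.n_categories
    freq_cum = np.cumsum(model.frequencies)
    length_cum = np.cumsum(indels.length_pmf())
    event_log: List[Tuple[str, str, int, int]] = []

    root_cats = rng.integers(K, size=root_length)
    root_res = np.searchsorted(freq_cum, rng.random(root_length))
    cols = [_Column(int(c)) for c in root_cats]
    for a, b in zip(cols, cols[1:]):
        a.next, b.prev = b, a
    head: List[Optional[_Column]] = [cols[0]]
    root_sites = [[c, int(r)] for c, r in zip(cols, root_res)]

    snapshots: Dict[str, List[List]] = {}

    def recurse(node, sites):
        label = Phylogeny.node_label(node)
        snapshots[label] = sites
        for child in node.child_nodes():
            child_sites = [[col, res] for col, res in sites]
            _evolve_branch(
                child_sites, Phylogeny.node_label(child), child.edge.length,
                model, indels, length_cum, rng, event_log, head,
            )
            recurse(child, child_sites)

    recurse(tree.root, root_sites)

    # walk the global column list; find true head (insertions may have prepended)
    first = head[0]
    while first.prev is not None:
        first = first.prev
    per_node: Dict[str, Dict[int, int]] = {
        label: {id(col): res for col, res in sites} for label, sites in snapshots.items()
    }
    ordered: List[_Column] = []
    col = first
    while col is not None:
        if any(id(col) in m for m in per_node.values()):
            ordered.append(col)
        col = col.next

    row_order = [Phylogeny.node_label(n) for n in tree.preorder()]
    alignment = {}
    for label in row_order:
        m = per_node[label]
        alignment[label] = "".join(
            AMINO_ACIDS[m[id(c)]] if id(c) in m else GAP for c in ordered
        )
    sequences = {label: row.replace(GAP, "") for label, row in alignment.items()}
    return EvolutionHistory(
        tree=tree,
        sequences=sequences,
        true_alignment=alignment,
        site_categories=[c.cat for c in ordered],
        event_log=event_log,
        row_order=row_order,
    )


def evolve(
    tree: Phylogeny,
    model: RateModel,
    indels: IndelParams,
    root_length: int = 408,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_retries: int = 100,
) -> EvolutionHistory:
    """Simulate sequences down ``tree`` and return the full evolution history.

    The root sequence is drawn i.i.d. from the stationary frequencies with
    i.i.d. gamma categories.  A replicate in which any lineage's sequence
    shrinks to length zero is rejected and re-simulated with a fresh
    sub-stream; the number of rejections is recorded on the history.
    """
    if root_length < 1:
        raise ConfigurationError(f"root_length must be >= 1, got {root_length!r}")
    indels.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_rejected = 0
    for _ in range(max_retries):
        try:
            history = _evolve_once(tree, model, indels, int(root_length), rng)
        except SimulationError:
            n_rejected += 1
            continue
        history.n_rejected = n_rejected
        return history
    raise SimulationError(f"replicate rejected {max_retries} times (sequence extinction)")


# -- FASTA writers ---------------------------------------------------------


def _fasta(records: List[Tuple[str, str]]) -> str:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    import io

    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records],
        buf,
        "fasta-2line",
    )
    return buf.getvalue()


def tip_fasta(history: EvolutionHistory) -> str:
    """Ungapped tip sequences as FASTA text."""
    tips = set(history.tree.tip_labels)
    return _fasta([(l, history.sequences[l]) for l in history.row_order if l in tips])


def ancestors_fasta(history: EvolutionHistory) -> str:
    """Ungapped ancestral (internal-node) sequences as FASTA text."""
    tips = set(history.tree.tip_labels)
    return _fasta([(l, history.sequences[l]) for l in history.row_order if l not in tips])


def true_alignment_fasta(history: EvolutionHistory) -> str:
    """The true all-node alignment as FASTA text (gap character '-')."""
    return _fasta([(l, history.true_alignment[l]) for l in history.row_order])
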