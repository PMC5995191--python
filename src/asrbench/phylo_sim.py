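"""Ultrametric birth-death tree simulation and Newick I/O.

Trees are simulated under a birth-death process with incomplete species
sampling, conditioned on the number of sampled tips.  Internal node ages are
drawn as order statistics from the conditional age kernel of the sampled
birth-death process: given ``n`` sampled tips, the ``n - 2`` non-root
divergence times are i.i.d. draws from the kernel density, sorted, and
attached by uniform random joins; the root sits at the requested tree
height.  This yields exactly ``n`` tips without rejection, which matters at
low sampling fractions.

Branch lengths are in expected substitutions per site; the root-to-tip
distance of every simulated tree equals the requested height.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Dict, Iterator, List

import dendropy
import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "TreeSimParams",
    "Phylogeny",
    "simulate_tree",
    "node_depths",
    "read_newick",
    "write_newick",
    "bd_kernel_pdf",
    "bd_kernel_cdf",
]


@dataclass(frozen=True)
class TreeSimParams:
    """Parameters of the sampled birth-death tree simulation.

    Attributes
    ----------
    n_taxa:
        Number of sampled tips (>= 2).
    height:
        Root-to-tip distance in expected substitutions per site.
    sampling_fraction:
        Probability rho in (0, 1] that an extant lineage is sampled.  Low
        values produce star-like trees whose divergences crowd the root.
    birth_rate, death_rate:
        Per-lineage speciation and extinction rates (lambda > mu >= 0).
    seed:
        Seed for the tree's random number stream.
    """

    n_taxa: int
    height: float
    sampling_fraction: float
    birth_rate: float = 6.0
    death_rate: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_taxa, (int, np.integer)) and self.n_taxa >= 2):
            raise ConfigurationError(f"n_taxa must be an integer >= 2, got {self.n_taxa!r}")
        if not self.height > 0:
            raise ConfigurationError(f"height must be > 0, got {self.height!r}")
        if not (0 < self.sampling_fraction <= 1):
            raise ConfigurationError(
                f"sampling_fraction must be in (0, 1], got {self.sampling_fraction!r}"
            )
        if not self.death_rate >= 0:
            raise ConfigurationError(f"death_rate must be >= 0, got {self.death_rate!r}")
        if not self.birth_rate > self.death_rate:
            raise ConfigurationError(
                "birth_rate must exceed death_rate, got "
                f"birth_rate={self.birth_rate!r}, death_rate={self.death_rate!r}"
            )


class Phylogeny:
    """A rooted binary tree with branch lengths, backed by a dendropy Tree.

    Tips carry labels; internal nodes are labeled "N1" (root) ... "Nk" in
    preorder so that true and reconstructed ancestors correspond by label.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def preorder(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_node_iter()

    def postorder(self) -> Iterator[dendropy.Node]:
        return self.tree.postorder_node_iter()

    @property
    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def internal_labels(self) -> List[str]:
        return [n.label for n in self.preorder() if not n.is_leaf()]

    @staticmethod
    def node_label(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def validate(self) -> None:
        for node in self.preorder():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise InputError(
                    f"node {self.node_label(node)!r} has {len(kids)} children; tree must be binary"
                )
            if node is not self.root and (node.edge.length is None or node.edge.length < 0):
                raise InputError(f"node {self.node_label(node)!r} has invalid branch length")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return write_newick(self) == write_newick(other)


# -- birth-death age kernel ------------------------------------------------


def _kernel_constants(birth: float, death: float, rho: float):
    a = birth - death  # net diversification
    c = rho * birth
    d = birth * (1.0 - rho) - death
    return a, c, d


def bd_kernel_pdf(t: np.ndarray, height: float, birth: float, death: float, rho: float) -> np.ndarray:
    """Density of a non-root divergence time at age ``t`` in (0, height).

    Ages are measured backwards from the tips (tips at 0, root at ``height``)
    under the sampled birth-death process conditioned on the root age.
    """
    t = np.asarray(t, dtype=float)
    a, c, d = _kernel_constants(birth, death, rho)
    u = np.exp(-a * t)
    dens = a * a * rho * u / (c + d * u) ** 2
    norm = _kernel_mass(height, birth, death, rho)
    return np.where((t >= 0) & (t <= height), dens / norm, 0.0)


def _kernel_mass(t: float, birth: float, death: float, rho: float) -> float:
    # integral of the unnormalized density from 0 to t (closed form)
    a, c, d = _kernel_constants(birth, death, rho)
    u = math.exp(-a * t)
    if abs(d) < 1e-14:
        return rho * a / c**2 * (1.0 - u)
    return rho * a / d * (1.0 / (c + d * u) - 1.0 / (c + d))


def bd_kernel_cdf(t: np.ndarray, height: float, birth: float, death: float, rho: float) -> np.ndarray:
    """CDF of the divergence-time kernel on (0, height)."""
    t = np.asarray(t, dtype=float)
    norm = _kernel_mass(height, birth, death, rho)
    mass = np.vectorize(lambda x: _kernel_mass(min(max(x, 0.0), height), birth, death, rho))(t)
    return mass / norm


def _sample_kernel_ages(n: int, height: float, birth: float, death: float, rho: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of divergence ages via the closed-form inverse."""
    a, c, d = _kernel_constants(birth, death, rho)
    q = rng.random(n)
    total = _kernel_mass(height, birth, death, rho)
    m = q * total  # target unnormalized mass
    if abs(d) < 1e-14:
        u = 1.0 - m * c**2 / (rho * a)
    else:
        inv = m * d / (rho * a) + 1.0 / (c + d)
        u = (1.0 / inv - c) / d
    t = -np.log(u) / a
    return np.clip(t, 0.0, height)


# -- tree construction -----------------------------------------------------


def simulate_tree(params: TreeSimParams) -> Phylogeny:
    """Simulate one ultrametric rooted binary tree with exactly ``n_taxa`` tips.

    The root is placed at ``params.height``; the remaining ``n_taxa - 2``
    divergence ages are i.i.d. draws from the sampled birth-death kernel,
    attached in descending age order by splitting a uniformly chosen active
    lineage (the uniform ranked-topology construction).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(params.n_taxa)

    ages = _sample_kernel_ages(
        n - 2, params.height, params.birth_rate, params.death_rate,
        params.sampling_fraction, rng,
    )
    ages = np.sort(ages)[::-1]  # oldest first

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    root.age_ = params.height

    active: List[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    for age in ages:
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.age_ = float(age)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    for leaf in active:
        leaf.age_ = 0.0

    # branch lengths from age differences; label tips and internal nodes in preorder
    tip_i = 0
    internal_i = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age_ - node.age_
        if node.is_leaf():
            tip_i += 1
            node.taxon = taxon_namespace.new_taxon(label=f"T{tip_i}")
        else:
            internal_i += 1
            node.label = f"N{internal_i}"

    phylo = Phylogeny(tree)
    _rescale_to_height(phylo, params.height)
    return phylo


def _rescale_to_height(phylo: Phylogeny, height: float) -> None:
    """Rescale all branch lengths so the root-to-tip distance is exactly ``height``."""
    depths = node_depths(phylo)
    tip_depths = [depths[leaf.taxon.label] for leaf in phylo.tree.leaf_node_iter()]
    current = max(tip_depths)
    if current <= 0:
        return
    factor = height / current
    for node in phylo.preorder():
        if node.parent_node is not None:
            node.edge.length *= factor


def node_depths(phylo: Phylogeny) -> Dict[str, float]:
    """Distance from the root for every node, keyed by node label."""
    depths: Dict[str, float] = {}
    for node in phylo.preorder():
        label = Phylogeny.node_label(node)
        if node.parent_node is None:
            depths[label] = 0.0
        else:
            parent_label = Phylogeny.node_label(node.parent_node)
            depths[label] = depths[parent_label] + node.edge.length
    return depths


# -- Newick I/O ------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phylo: Phylogeny) -> str:
    """Serialize to Newick with internal labels and full-precision branch lengths."""
    buf = io.StringIO()
    phylo.tree.write(
        file=buf,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return buf.getvalue().strip()
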