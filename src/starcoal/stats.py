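"""Summary statistics capturing how star-like a haplogroup phylogeny is.

Three measures are computed on a tree rescaled to total branch length 1.0:

* ``r`` — the singleton/shared ratio: total terminal branch length divided
  by a weighted sum of internal branch lengths, where each internal branch
  is weighted by one plus the internal branch length beneath its node.
  A perfect star has no internal branches and ``r = +inf``.
* ``m`` — the mean pairwise-TMRCA depth over all C(n,2) tip pairs.
* ``d`` — the population standard deviation of those depths; zero exactly
  when every pair coalesces at the same depth (a star).

Together they summarise the time depth of the tree and how star-like its
shape is, which is what distinguishes an explosive expansion (short
internal branches, uniform pair depths) from a gradual one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy

from .treeio import normalize, total_length

__all__ = [
    "StatVector",
    "singleton_shared_ratio",
    "pairwise_tmrca_depths",
    "stat_vector",
]


@dataclass(frozen=True)
class StatVector:
    """The (r, mean TMRCA, SD TMRCA) triple on a normalized tree."""

    r: float
    tmrca_mean: float
    tmrca_sd: float

    def __iter__(self):
        return iter((self.r, self.tmrca_mean, self.tmrca_sd))

    @property
    def is_finite(self) -> bool:
        return all(math.isfinite(v) for v in self)


def _is_internal_branch(node) -> bool:
    # internal = non-root, non-terminal: the branch above an internal node
    return node.parent_node is not None and not node.is_leaf()


def singleton_shared_ratio(tree: dendropy.Tree, include_terminal_below: bool = False) -> float:
    """Singleton/shared ratio ``r`` of a rooted tree.

    ``r = sum(terminal l_b) / sum_internal(l_b * (1 + S_b))`` where
    ``S_b`` sums the internal branch lengths strictly beneath branch
    ``b``'s child node.  With ``include_terminal_below=True`` the inner
    sum counts terminal branches too (a stricter "all branches beneath"
    reading; off by default).

    Returns ``+inf`` for a tree with no internal branches (perfect star);
    ``r`` is not scale-invariant (the ``1 +`` weighting), so callers that
    want the canonical statistic should pass a normalized tree — which is
    what :func:`stat_vector` does.
    """
    term = 0.0
    denom = 0.0
    below: dict = {}
    # postorder: children processed before parents
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = 0.0
            if node.parent_node is not None:
                term += node.edge.length or 0.0
            continue
        s = 0.0
        for child in node.child_nodes():
            s += below[child]
            length = child.edge.length or 0.0
            if not child.is_leaf() or include_terminal_below:
                s += length
        below[node] = s
        if node.parent_node is not None:
            denom += (node.edge.length or 0.0) * (1.0 + s)
    if denom <= 0.0:
        return math.inf
    return term / denom


def pairwise_tmrca_depths(tree: dendropy.Tree) -> list:
    """Depth of the MRCA of every unordered tip pair (C(n,2) values).

    The depth of a pair is the mean path length from their MRCA down to
    the two tips; on an ultrametric tree the two paths are equal and this
    is simply the MRCA's height above the tips.
    """
    leaves = tree.leaf_nodes()
    n = len(leaves)
    if n < 2:
        raise ValueError("need at least two tips for pairwise depths")
    # depth-from-root of every node, then pair depths via MRCA
    dist = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
    ancestors = {}
    for lf in leaves:
        chain = []
        node = lf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors[lf] = chain
    depths = []
    for i in range(n):
        anc_i = set(ancestors[leaves[i]])
        for j in range(i + 1, n):
            mrca = next(nd for nd in ancestors[leaves[j]] if nd in anc_i)
            depth = 0.5 * ((dist[leaves[i]] - dist[mrca]) + (dist[leaves[j]] - dist[mrca]))
            depths.append(depth)
    return depths


def stat_vector(tree: dendropy.Tree) -> StatVector:
    """Compute the three statistics on the total-length-1.0 rescaling of ``tree``."""
    if total_length(tree) <= 0:
        raise ValueError("tree has zero total branch length")
    norm = normalize(tree)
    depths = pairwise_tmrca_depths(norm)
    n_pairs = len(depths)
    mean = sum(depths) / n_pairs
    var = sum((x - mean) ** 2 for x in depths) / n_pairs  # population SD
    return StatVector(
        r=singleton_shared_ratio(norm),
        tmrca_mean=mean,
        tmrca_sd=math.sqrt(var),
    )
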