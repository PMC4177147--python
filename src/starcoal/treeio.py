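"""Tree I/O and manipulation for haplogroup phylogenies.

Trees are rooted, may contain polytomies, and carry non-negative branch
lengths whose unit depends on context: SNP counts on observed haplogroup
trees, generations on simulated genealogies, or dimensionless units after
normalization.  The in-memory representation is :class:`dendropy.Tree`;
this module adds the domain operations (pedigree collapsing, total-length
normalization) and access to the packaged haplogroup fixtures.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import dendropy

__all__ = [
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "total_length",
    "collapse_pedigree",
    "collapse_zero_internal",
    "normalize",
    "EmpiricalFixture",
    "load_fixture",
    "FIXTURE_FILES",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Polytomies are allowed; a trifurcation at the top level is read as a
    rooted polytomy (haplogroup trees are rooted, so no unrooted
    reinterpretation takes place).  Lines starting with ``#`` are treated
    as comments and skipped, which lets fixture files carry a provenance
    header.

    Raises
    ------
    NewickParseError
        If the string is malformed; the message names the approximate
        character position when the underlying parser reports one.
    """
    payload = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("#")
    ).strip()
    if not payload:
        raise NewickParseError("empty Newick input")
    # cheap structural pre-check so errors carry a character position
    depth = 0
    for pos, ch in enumerate(payload):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character {pos} in Newick string"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(' (depth {depth} at end of string, length {len(payload)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=payload,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    if len(tree.leaf_nodes()) == 0:
        raise NewickParseError("Newick string contains no leaves")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a one-line Newick string with branch lengths."""
    leaves = tree.leaf_nodes()
    if len(leaves) == 0:
        raise ValueError("cannot serialize an empty tree")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return s


def read_newick_file(path) -> dendropy.Tree:
    """Read a Newick tree from ``path`` (``#`` header lines are skipped)."""
    with open(path) as fh:
        return parse_newick(fh.read())


def total_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (the root's edge, if any, is excluded)."""
    tot = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            tot += node.edge.length
    return tot


def _leaf_labels(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def collapse_pedigree(tree: dendropy.Tree, pedigree_tips) -> dendropy.Tree:
    """Collapse a clade of related individuals into a single tip.

    Individuals from one pedigree violate the coalescent assumption of
    unrelated samples, so their clade is replaced by one representative
    branch whose length is the SNP count on the clade's stem branch
    (variants shared by every member) plus the mean, over members, of each
    member's own SNP count measured from the clade ancestor.

    ``pedigree_tips`` must be the complete leaf set of a clade.  The clade
    node is taken as the highest node whose leaf set equals
    ``pedigree_tips``, so a unary chain above a single member contributes
    its stem branch as the shared count.
    """
    tips = set(pedigree_tips)
    if not tips:
        raise ValueError("pedigree tip set is empty")
    work = tree.clone(depth=1)
    labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    missing = tips - labels
    if missing:
        raise ValueError(f"pedigree tips not in tree: {sorted(missing)}")

    clade_node = None
    for node in work.preorder_node_iter():  # preorder => first hit is highest
        if _leaf_labels(node) == tips:
            clade_node = node
            break
    if clade_node is None:
        raise ValueError("pedigree tips do not form a clade")
    if clade_node.parent_node is None:
        raise ValueError("pedigree clade is the whole tree; nothing to attach to")

    stem = clade_node.edge.length or 0.0
    private = []
    for lf in clade_node.leaf_iter():
        d = 0.0
        n = lf
        while n is not clade_node:
            d += n.edge.length or 0.0
            n = n.parent_node
        private.append(d)
    new_len = stem + sum(private) / len(private)

    parent = clade_node.parent_node
    parent.remove_child(clade_node)
    label = sorted(tips)[0] + "_ped" if len(tips) > 1 else sorted(tips)[0]
    taxon = dendropy.Taxon(label=label)
    work.taxon_namespace.add_taxon(taxon)
    parent.new_child(taxon=taxon, edge_length=new_len)
    work.update_bipartitions(suppress_unifurcations=False)
    return work


def normalize(tree: dendropy.Tree, tol: float = 1e-12) -> dendropy.Tree:
    """Return a copy rescaled to total branch length 1.0.

    Topology is untouched; every branch is divided by the original total.
    Raises ``ValueError`` on a degenerate (zero total length) tree.
    """
    tot = total_length(tree)
    if tot <= 0.0:
        raise ValueError("tree has zero total branch length; cannot normalize")
    if abs(tot - 1.0) <= tol:
        return tree.clone(depth=1)
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            node.edge.length = node.edge.length / tot
    return out


def collapse_zero_internal(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse internal branches of length 0 into polytomies.

    On SNP-count trees an internal branch that carries no variant is
    unobservable, so the corresponding node is merged with its parent.
    Terminal branches are never removed.
    """
    out = tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder_node_iter()):
            if (
                node.parent_node is not None
                and not node.is_leaf()
                and (node.edge.length or 0.0) == 0.0
            ):
                parent = node.parent_node
                for child in list(node.child_nodes()):
                    node.remove_child(child)
                    parent.add_child(child)
                parent.remove_child(node)
                changed = True
    return out


# ---------------------------------------------------------------------------
# Packaged haplogroup fixtures
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "R1b": "r1b_synthetic.nwk",
    "E1b1a": "e1b1a_synthetic.nwk",
}


@dataclass(frozen=True)
class EmpiricalFixture:
    """A packaged haplogroup tree with integer SNP branch lengths.

    The R1b tree is a near-star over 6 chromosomes (a single internal
    branch of one SNP unites three of them); the E1b1a tree over 8
    chromosomes is bifurcating apart from one trifurcation and has greater
    time depth.  These are synthetic stand-ins: trees drawn from the
    package's own simulator under the best-supported expansion regime for
    each continent, constrained to reproduce the published tree structures
    (see the files' provenance headers).
    """

    haplogroup: str
    tree: dendropy.Tree
    n_tips: int
    provenance: str


def load_fixture(haplogroup: str) -> EmpiricalFixture:
    """Load the packaged tree for ``"R1b"`` or ``"E1b1a"``."""
    try:
        fname = FIXTURE_FILES[haplogroup]
    except KeyError:
        raise ValueError(
            f"unknown haplogroup {haplogroup!r}; expected one of {sorted(FIXTURE_FILES)}"
        ) from None
    ref = importlib.resources.files("starcoal") / "data" / fname
    text = ref.read_text()
    provenance = "\n".join(
        line.lstrip("# ").rstrip()
        for line in text.splitlines()
        if line.lstrip().startswith("#")
    )
    tree = parse_newick(text)
    return EmpiricalFixture(
        haplogroup=haplogroup,
        tree=tree,
        n_tips=len(tree.leaf_nodes()),
        provenance=provenance,
    )
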