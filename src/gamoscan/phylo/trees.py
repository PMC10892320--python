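"""Unrooted binary tree topologies: representation, enumeration, Newick.

A topology is stored in "pseudo-rooted" form: a nested tuple whose top level
has three subtrees (the standard unrooted representation); every other
internal node is binary.  Branch lengths are keyed by bipartition — the
frozenset of leaf labels on the side of the edge *not* containing the
lexicographically smallest leaf — which is stable under re-rooting.

Exhaustive enumeration proceeds by stepwise leaf addition (each unrooted
binary tree on n labelled leaves arises exactly once when leaves are added
in a fixed order onto each of the 2k-3 edges), giving (2n-5)!! topologies.
Constrained subtrees are collapsed to super-leaves before enumeration and
re-expanded afterwards, the same device the source analyses use to keep the
search space at 15 trees for five effective OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

Subtree = Union[str, tuple]  # leaf label or tuple of subtrees


def leaf_set(tree: Subtree) -> frozenset[str]:
    if isinstance(tree, str):
        return frozenset([tree])
    out: set[str] = set()
    for child in tree:
        out |= leaf_set(child)
    return frozenset(out)


def edge_key(side: Iterable[str], all_leaves: Iterable[str]) -> frozenset[str]:
    """Canonical bipartition key: the side not containing the smallest leaf."""
    side = frozenset(side)
    leaves = frozenset(all_leaves)
    if min(leaves) in side:
        side = leaves - side
    return side


@dataclass(frozen=True)
class TreeTopology:
    """An unrooted binary topology over a fixed leaf set."""

    structure: tuple  # top-level 3-tuple of subtrees (2-tuple allowed for n=2)

    def __post_init__(self) -> None:
        labels = sorted(leaf_set(self.structure))
        if len(labels) != len(list(_iter_leaves(self.structure))):
            raise ValueError("duplicate leaf labels")
        if len(labels) >= 3 and len(self.structure) != 3:
            raise ValueError("unrooted topology must have a trifurcating top level")
        _check_binary(self.structure, top=True)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(leaf_set(self.structure)))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions (internal edges), canonically keyed."""
        leaves = leaf_set(self.structure)
        found: set[frozenset[str]] = set()

        def walk(node: Subtree) -> None:
            if isinstance(node, str):
                return
            for child in node:
                side = leaf_set(child)
                if 2 <= len(side) <= len(leaves) - 2:
                    found.add(edge_key(side, leaves))
                walk(child)

        walk(self.structure)
        return frozenset(found)

    def edges(self) -> list[frozenset[str]]:
        """All edges (terminal and internal) as bipartition keys."""
        leaves = leaf_set(self.structure)
        out: list[frozenset[str]] = []

        def walk(node: Subtree) -> None:
            if isinstance(node, str):
                return
            for child in node:
                out.append(edge_key(leaf_set(child), leaves))
                walk(child)

        walk(self.structure)
        # deduplicate (the three top-level edges can repeat keys only for n=2)
        seen: list[frozenset[str]] = []
        for k in out:
            if k not in seen:
                seen.append(k)
        return seen

    @property
    def canonical_id(self) -> str:
        parts = sorted(",".join(sorted(s)) for s in self.splits())
        return "{" + ";".join(parts) + "}@(" + ",".join(self.leaves) + ")"

    def contains_split(self, side: Iterable[str]) -> bool:
        return edge_key(side, leaf_set(self.structure)) in self.splits()

    def newick(self, branch_lengths: Optional[dict[frozenset[str], float]] = None,
               support: Optional[dict[frozenset[str], float]] = None) -> str:
        leaves = leaf_set(self.structure)

        def fmt(node: Subtree) -> str:
            if isinstance(node, str):
                label = node
            else:
                label = "(" + ",".join(fmt(c) for c in node) + ")"
                if support is not None:
                    key = edge_key(leaf_set(node), leaves)
                    if key in support:
                        label += f"{support[key]:.2f}"
            if branch_lengths is not None:
                key = edge_key(leaf_set(node), leaves)
                if key in branch_lengths:
                    label += f":{branch_lengths[key]:.6f}"
            return label

        return "(" + ",".join(fmt(c) for c in self.structure) + ");"

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeTopology({self.newick()})"


def _iter_leaves(tree: Subtree):
    if isinstance(tree, str):
        yield tree
    else:
        for child in tree:
            yield from _iter_leaves(child)


def _check_binary(node: Subtree, top: bool = False) -> None:
    if isinstance(node, str):
        return
    if not top and len(node) != 2:
        raise ValueError("internal nodes must be binary")
    for child in node:
        _check_binary(child)


def _insert_everywhere(tree: tuple, leaf: Subtree) -> list[tuple]:
    """All trees obtained by attaching `leaf` onto each edge of `tree`."""

    def insert_in_subtree(node: Subtree) -> list[Subtree]:
        # returns variants of `node` with the leaf inserted somewhere inside
        # (not on the edge above `node` itself)
        if isinstance(node, str):
            return []
        variants: list[Subtree] = []
        for i, child in enumerate(node):
            # on the edge above child
            new = list(node)
            new[i] = (child, leaf)
            variants.append(tuple(new))
            # deeper inside child
            for sub in insert_in_subtree(child):
                new = list(node)
                new[i] = sub
                variants.append(tuple(new))
        return variants

    return [t for t in insert_in_subtree(tree)]  # type: ignore[misc]


def enumerate_topologies(
    leaves: Sequence[str],
    constraints: Optional[Sequence[Subtree]] = None,
) -> list[TreeTopology]:
    """All distinct unrooted binary topologies, honouring fixed subtrees.

    `constraints` are resolved rooted subtrees (nested tuples of labels, e.g.
    ``((("YC-IV", "HT-IV"), "ATCC30299"), "R1072")``) over disjoint leaf
    subsets; each is collapsed to one effective OTU.  The result has
    (2m-5)!! members for m effective leaves.
    """
    leaves = list(leaves)
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    constraints = list(constraints or [])
    covered: set[str] = set()
    for sub in constraints:
        ls = leaf_set(sub)
        if ls & covered:
            raise ValueError("constraints overlap in leaves")
        if not ls <= set(leaves):
            raise ValueError("constraint uses labels not in the leaf list")
        if len(ls) < 2:
            raise ValueError("constraints must contain at least two leaves")
        covered |= ls

    # constraints become atomic placeholder leaves so stepwise insertion
    # cannot break them apart; expanded back after enumeration
    placeholders: dict[str, Subtree] = {}
    tokens: list[str] = [l for l in leaves if l not in covered]
    for i, sub in enumerate(constraints):
        name = f"\x00constraint{i}\x00"
        placeholders[name] = _as_tuple(sub)
        tokens.append(name)
    m = len(tokens)
    if m < 3:
        raise ValueError("need at least three effective leaves")

    trees: list[tuple] = [tuple(tokens[:3])]
    for tok in tokens[3:]:
        trees = [t for tree in trees for t in _insert_everywhere(tree, tok)]

    def expand(node: Subtree) -> Subtree:
        if isinstance(node, str):
            return placeholders.get(node, node)
        return tuple(expand(c) for c in node)

    out: list[TreeTopology] = []
    seen: set[str] = set()
    for t in trees:
        topo = TreeTopology(expand(t))
        if topo.canonical_id not in seen:
            seen.add(topo.canonical_id)
            out.append(topo)
    out.sort(key=lambda t: t.canonical_id)
    return out


def _as_tuple(node: Subtree) -> Subtree:
    if isinstance(node, str):
        return node
    return tuple(_as_tuple(c) for c in node)


def parse_newick_subtree(text: str) -> Subtree:
    """Parse a rooted Newick subtree (e.g. a topology constraint) verbatim."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(node) -> Subtree:
        if node.is_leaf():
            return node.taxon.label
        return tuple(convert(c) for c in node.child_nodes())

    return convert(tree.seed_node)


def parse_newick(text: str) -> tuple[TreeTopology, dict[frozenset[str], float]]:
    """Parse a Newick string into a topology plus bipartition-keyed lengths.

    Rooted (bifurcating top level) inputs are unrooted by merging the root's
    two children; the two root-adjacent branch lengths are summed onto the
    single unrooted edge, the usual convention.
    """
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = False

    def convert(node) -> Subtree:
        if node.is_leaf():
            return node.taxon.label
        return tuple(convert(c) for c in node.child_nodes())

    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2:
        tree.collapse_basal_bifurcation()
        root_children = tree.seed_node.child_nodes()
    structure = tuple(convert(c) for c in root_children)
    topo = TreeTopology(structure)
    leaves = leaf_set(structure)
    lengths: dict[frozenset[str], float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        side = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        key = edge_key(side, leaves)
        lengths[key] = lengths.get(key, 0.0) + float(edge.length)
    return topo, lengths
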