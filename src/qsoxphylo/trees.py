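"""Leaf-labeled trees with branch lengths and integer-percent supports.

A light rooted data structure; unrooted trees (e.g. neighbor-joining output)
are represented with a trifurcating root, the standard convention.  Newick
text is parsed with dendropy and converted; writing is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch above this node
    support: int | None = None   # integer percent on the edge above
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]


class Tree:
    """A leaf-labeled tree; `rooted=False` marks trifurcating-root unrooted trees."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf labels are not unique")

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    def postorder(self):
        return self.root.postorder()

    # -- newick -----------------------------------------------------------
    def _write(self, node: Node) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(self._write(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            body = f"({inner}){label}"
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    def newick(self) -> str:
        return self._write(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Tree":
        import dendropy
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def conv(dn) -> Node:
            node = Node(
                name=dn.taxon.label.replace(" ", "_") if dn.taxon else None,
                length=dn.edge.length,
                children=[conv(c) for c in dn.child_nodes()],
            )
            if dn.label is not None and not dn.is_leaf():
                try:
                    node.support = int(round(float(dn.label)))
                except ValueError:
                    node.name = dn.label
            return node

        return cls(conv(dt.seed_node), rooted=rooted)

    # -- bipartitions -----------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each encoded canonically as the side
        that excludes the lexicographically smallest leaf."""
        all_leaves = self.leaf_set
        ref = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = all_leaves - below if ref in below else below
                out.add(side)
            return below

        walk(self.root)
        return out

    def clade_supports(self) -> dict[frozenset, int | None]:
        """Map canonical bipartition -> support on the corresponding edge."""
        all_leaves = self.leaf_set
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset, int | None] = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = all_leaves - below if ref in below else below
                out[side] = node.support
            return below

        walk(self.root)
        return out

    def set_supports(self, values: dict[frozenset, int]) -> None:
        """Write integer supports onto edges keyed by canonical bipartition."""
        all_leaves = self.leaf_set
        ref = min(all_leaves)
        n = len(all_leaves)

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = all_leaves - below if ref in below else below
                if side in values:
                    node.support = values[side]
            return below

        walk(self.root)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by id(node)."""
        out = {id(self.root): 0.0}

        def walk(node: Node, d: float):
            for c in node.children:
                dc = d + (c.length or 0.0)
                out[id(c)] = dc
                walk(c, dc)

        walk(self.root, 0.0)
        return out

    def scaled(self, factor: float) -> "Tree":
        """A copy with every branch length multiplied by *factor*."""

        def conv(node: Node) -> Node:
            return Node(node.name,
                        None if node.length is None else node.length * factor,
                        node.support, [conv(c) for c in node.children])

        return Tree(conv(self.root), rooted=self.rooted)

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        d = self.depths()
        return max(d[id(n)] for n in self.root.leaves())

    def patristic(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path-length distances keyed by (name_a, name_b)."""
        paths: dict[str, list[Node]] = {}

        def walk(node: Node, path: list[Node]):
            path = path + [node]
            if node.is_leaf:
                paths[node.name] = path
            for c in node.children:
                walk(c, path)

        walk(self.root, [])
        depth = self.depths()
        out: dict[tuple[str, str], float] = {}
        names = sorted(paths)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pa, pb = paths[a], paths[b]
                lca = None
                for x, y in zip(pa, pb):
                    if x is y:
                        lca = x
                    else:
                        break
                d = depth[id(pa[-1])] + depth[id(pb[-1])] - 2 * depth[id(lca)]
                out[(a, b)] = out[(b, a)] = d
        return out

    def k_deepest_clades(self, k: int) -> list[list[str]]:
        """Partition leaves into k monophyletic groups by repeatedly splitting
        the group whose root is closest to the tree root (deterministic)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if k == 1:
            return [self.leaf_names()]
        depth = self.depths()
        order: dict[int, int] = {}

        def number(node: Node):
            order[id(node)] = len(order)
            for c in node.children:
                number(c)

        number(self.root)
        groups: list[Node] = [self.root]
        while len(groups) < k:
            splittable = [g for g in groups if not g.is_leaf]
            if not splittable:
                break
            g = min(splittable, key=lambda n: (depth[id(n)], order[id(n)]))
            groups.remove(g)
            groups.extend(g.children)
        return [[leaf.name for leaf in g.leaves()] for g in groups]
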