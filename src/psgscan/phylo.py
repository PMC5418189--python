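"""Rooted/unrooted tree container with branch labels for selection scans.

Trees are stored as simple linked nodes. Each edge (identified with the
node below it) carries a length in expected substitutions per site and an
optional *foreground* flag. The newick reader and writer understand the
codeml-style ``#1`` suffix that marks foreground branches, e.g.::

    ((A,B)#1:0.1,C:0.2,D:0.3);   # the AB stem edge is foreground
    ((A#1:0.1,B:0.1):0.05,C:0.2,D:0.3);   # the terminal edge to A

Everything downstream (the branch-site likelihood, tree estimation,
consensus) works on this structure.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator


class Node:
    __slots__ = ("name", "length", "children", "parent", "foreground")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.foreground = False

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name or '<internal>'}, t={self.length:g})"


class Tree:
    """A phylogenetic tree; the root's branch length is ignored."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def parse(cls, newick: str) -> "Tree":
        s = newick.strip()
        if not s.endswith(";"):
            raise ValueError("newick string must end with ';'")
        s = s[:-1].strip()
        pos = 0

        def parse_node() -> Node:
            nonlocal pos
            node = Node()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse_node())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise ValueError(f"unexpected character {s[pos]!r} at {pos}")
            # label, optional #tag, optional :length — in any sane order
            m = re.match(r"[^,():;#\[\]]*", s[pos:])
            node.name = m.group().strip().strip("'\"")
            pos += m.end()
            while pos < len(s) and s[pos] in "#: \t":
                if s[pos] in " \t":
                    pos += 1
                    continue
                if s[pos] == "#":
                    m = re.match(r"#\s*(\d+)", s[pos:])
                    if not m:
                        raise ValueError(f"malformed branch tag at {pos}")
                    if int(m.group(1)) > 0:
                        node.foreground = True
                    pos += m.end()
                else:
                    m = re.match(r":\s*([0-9.eE+-]+)", s[pos:])
                    if not m:
                        raise ValueError(f"malformed branch length at {pos}")
                    node.length = float(m.group(1))
                    pos += m.end()
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick at {pos}: {s[pos:]!r}")
        return cls(root)

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.parse(fh.read())

    def to_newick(self, lengths: bool = True, tags: bool = True, digits: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                out = node.name
            else:
                out = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if tags and node.foreground:
                out += " #1"
            if lengths and node.parent is not None:
                out += f":{node.length:.{digits}g}"
            return out

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def nodes(self) -> list:
        return list(self.postorder())

    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list:
        return [n.name for n in self.leaves()]

    def edges(self) -> list:
        """All nodes except the root (each identifies the edge above it)."""
        return [n for n in self.postorder() if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            c.foreground = node.foreground
            for child in node.children:
                c.add(clone(child))
            return c

        return Tree(clone(self.root))

    # ------------------------------------------------------- manipulation
    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, names: Iterable[str]) -> Node:
        names = list(names)
        target = set(names)
        missing = target - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        below: dict[int, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name} & target
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if below[id(node)] == target:
                return node
        raise RuntimeError("unreachable")  # pragma: no cover

    def clear_foreground(self) -> None:
        for n in self.postorder():
            n.foreground = False

    def set_foreground(self, names: Iterable[str], descendants: bool = False) -> Node:
        """Mark the edge above the MRCA of ``names`` as foreground.

        With ``descendants=True`` every edge inside the clade is marked too.
        Marking replaces any existing foreground labelling.
        """
        self.clear_foreground()
        node = self.mrca(names)
        if node is self.root:
            raise ValueError("foreground clade spans the whole tree (root has no branch)")
        node.foreground = True
        if descendants:
            stack = list(node.children)
            while stack:
                n = stack.pop()
                n.foreground = True
                stack.extend(n.children)
        return node

    def foreground_edges(self) -> list:
        return [n for n in self.edges() if n.foreground]

    def prune_to(self, names: Iterable[str]) -> "Tree":
        """Restriction of the tree to a leaf subset, suppressing unary nodes.

        Foreground flags survive: a suppressed unary chain is foreground if
        any merged edge was. Lengths along merged chains add.
        """
        keep = set(names)
        missing = keep - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name not in keep:
                    return None
                c = Node(node.name, node.length)
                c.foreground = node.foreground
                return c
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kid = kids[0]
                kid.length += node.length
                kid.foreground = kid.foreground or node.foreground
                return kid
            c = Node(node.name, node.length)
            c.foreground = node.foreground
            for k in kids:
                c.add(k)
            return c

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("no requested leaves present")
        # a root left with a single child is collapsed into that child
        while len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = 0.0
        return Tree(new_root)

    # ------------------------------------------------------- bipartitions
    def bipartitions(self, trivial: bool = False) -> dict:
        """Map each edge's leaf split to its branch length.

        A split is the frozenset of leaf names on the child side, normalized
        to the side *not* containing the lexicographically smallest leaf, so
        splits are comparable across rootings. Trivial splits (single leaf /
        all-but-one) are included only on request.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, float] = {}
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node.parent is None:
                continue
            side = below[id(node)]
            if anchor in side:
                side = all_leaves - side
            if not trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            if side in out:
                out[side] += node.length  # same split from both sides of the root
            else:
                out[side] = node.length
        return out


def robinson_foulds(tree_a: Tree, tree_b: Tree) -> int:
    """Unrooted symmetric-difference (RF) distance between two trees."""
    if set(tree_a.leaf_names()) != set(tree_b.leaf_names()):
        raise ValueError("trees are on different leaf sets")
    a = set(tree_a.bipartitions())
    b = set(tree_b.bipartitions())
    return len(a ^ b)
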