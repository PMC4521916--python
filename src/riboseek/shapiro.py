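"""Coarse-grained (Shapiro) tree representation and ordered tree edit distance.

A secondary structure is abstracted into an ordered, labelled tree whose
nodes are structural motifs rather than individual base pairs:

    R  virtual root
    E  external single-stranded region
    S  stem (maximal helix of stacked pairs)
    H  hairpin loop
    B  bulge (one-sided unpaired interruption between stems)
    I  interior loop (two-sided interruption)
    M  multibranch loop (>= 2 daughter stems)

The unweighted grain is used: nodes carry no size annotations, so the tree
captures the *shape* of the molecule only.  Consequently the tree is
invariant under compensatory base-pair substitutions, which is exactly the
conserved signal a structure-based homology search relies on.

The distance between trees is the ordered tree edit distance with unit
insert/delete/relabel costs (Zhang & Shasha's algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .structures import SecondaryStructure

SHAPIRO_LABELS = frozenset("RESHIBM")


@dataclass
class ShapiroNode:
    label: str
    children: list = field(default_factory=list)

    def __str__(self):
        if self.children:
            return self.label + "(" + ",".join(str(c) for c in self.children) + ")"
        return self.label


@dataclass
class ShapiroTree:
    """An ordered labelled motif tree rooted at the virtual node R."""

    root: ShapiroNode

    def __str__(self):
        return str(self.root)

    def __eq__(self, other):
        return isinstance(other, ShapiroTree) and str(self) == str(other)

    def size(self) -> int:
        return sum(1 for _ in self.iter_preorder())

    def iter_preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def labels_preorder(self) -> str:
        return "".join(n.label for n in self.iter_preorder())

    @classmethod
    def from_string(cls, text: str) -> "ShapiroTree":
        """Parse the compact string form, e.g. ``"R(S(M(S(H),S(H))))"``."""
        pos = 0

        def parse() -> ShapiroNode:
            nonlocal pos
            label = text[pos]
            if label not in SHAPIRO_LABELS:
                raise ValueError(f"bad label {label!r} at position {pos}")
            pos += 1
            node = ShapiroNode(label)
            if pos < len(text) and text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == ")":
                        pos += 1
                        break
            return node

        root = parse()
        if pos != len(text):
            raise ValueError(f"trailing characters at position {pos}")
        if root.label != "R":
            raise ValueError("tree must be rooted at R")
        return cls(root)


def shapiro_tree(s: SecondaryStructure) -> ShapiroTree:
    """Decompose a structure into its coarse-grained motif tree.

    Deterministic: maximal helices become S nodes (a lonely pair is a
    one-pair stem), the loop each helix closes becomes H/B/I/M, and maximal
    external unpaired runs become E children of the root, all in 5'->3'
    order.
    """
    partner = s.partner
    n = len(s)

    def build_helix(i: int, j: int) -> ShapiroNode:
        # (i, j) is the outermost pair of a helix; walk down the stack
        while i + 1 < j - 1 and partner.get(i + 1) == j - 1:
            i, j = i + 1, j - 1
        # classify the loop enclosed by the innermost pair (i, j)
        branches = []
        k = i + 1
        while k < j:
            if k in partner:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not branches:
            child = ShapiroNode("H")
        elif len(branches) == 1:
            (a, b), = branches
            left = a - (i + 1)
            right = (j - 1) - b
            label = "I" if (left > 0 and right > 0) else "B"
            child = ShapiroNode(label, [build_helix(a, b)])
        else:
            child = ShapiroNode("M", [build_helix(a, b) for a, b in branches])
        return ShapiroNode("S", [child])

    children = []
    k = 0
    while k < n:
        if k in partner:
            children.append(build_helix(k, partner[k]))
            k = partner[k] + 1
        else:
            run_start = k
            while k < n and k not in partner:
                k += 1
            children.append(ShapiroNode("E"))
            del run_start
    if not children:  # zero-length structure cannot occur, but be safe
        children = [ShapiroNode("E")]
    return ShapiroTree(ShapiroNode("R", children))


def element_string(s: SecondaryStructure) -> str:
    """Per-position motif labels (one of E/S/H/B/I/M for every residue).

    Paired positions are labelled S; unpaired positions carry the label of
    the loop (or external region) they belong to.  Used for the coarse
    motif-region comparison during candidate vetting.
    """
    partner = s.partner
    n = len(s)
    out = ["E"] * n
    for i in range(n):
        if i in partner:
            out[i] = "S"

    def fill_loop(i: int, j: int):
        # innermost pair of the helix starting at (i, j)
        while i + 1 < j - 1 and partner.get(i + 1) == j - 1:
            i, j = i + 1, j - 1
        branches = []
        k = i + 1
        while k < j:
            if k in partner:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not branches:
            label = "H"
        elif len(branches) == 1:
            (a, b), = branches
            label = "I" if (a - (i + 1) > 0 and (j - 1) - b > 0) else "B"
        else:
            label = "M"
        k = i + 1
        while k < j:
            if k in partner:
                k = partner[k] + 1
            else:
                out[k] = label
                k += 1
        for a, b in branches:
            fill_loop(a, b)

    k = 0
    while k < n:
        if k in partner:
            fill_loop(k, partner[k])
            k = partner[k] + 1
        else:
            k += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Zhang-Shasha ordered tree edit distance (unit costs)
# ---------------------------------------------------------------------------


def _postorder(root: ShapiroNode):
    """Postorder node list and leftmost-leaf-descendant index per node."""
    nodes: list[ShapiroNode] = []
    lml: list[int] = []

    def walk(node: ShapiroNode) -> int:
        if not node.children:
            nodes.append(node)
            lml.append(len(nodes) - 1)
            return len(nodes) - 1
        first = None
        for c in node.children:
            idx = walk(c)
            if first is None:
                first = lml[idx]
        nodes.append(node)
        lml.append(first)
        return len(nodes) - 1

    walk(root)
    return nodes, lml


def _keyroots(lml: list[int]) -> list[int]:
    seen = {}
    for i, l in enumerate(lml):
        seen[l] = i  # keep the highest postorder index per leftmost leaf
    return sorted(seen.values())


def tree_edit_distance(a: ShapiroTree, b: ShapiroTree) -> int:
    """Minimum number of node insertions, deletions and relabelings
    converting one ordered labelled tree into the other.

    Unit cost for every operation; a relabel between identical labels is
    free.  This is a metric on trees up to label-isomorphism.
    """
    an, al = _postorder(a.root)
    bn, bl = _postorder(b.root)
    m, n = len(an), len(bn)
    kr_a, kr_b = _keyroots(al), _keyroots(bl)
    td = [[0] * n for _ in range(m)]

    for i in kr_a:
        for j in kr_b:
            # forest distance over subforests rooted toward keyroots i, j
            ioff, joff = al[i], bl[j]
            fm, fn = i - ioff + 2, j - joff + 2
            fd = [[0] * fn for _ in range(fm)]
            for x in range(1, fm):
                fd[x][0] = fd[x - 1][0] + 1
            for y in range(1, fn):
                fd[0][y] = fd[0][y - 1] + 1
            for x in range(1, fm):
                for y in range(1, fn):
                    ni, nj = ioff + x - 1, joff + y - 1
                    if al[ni] == ioff and bl[nj] == joff:
                        cost = 0 if an[ni].label == bn[nj].label else 1
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[x - 1][y - 1] + cost,
                        )
                        td[ni][nj] = fd[x][y]
                    else:
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[al[ni] - ioff][bl[nj] - joff] + td[ni][nj],
                        )
    return td[m - 1][n - 1]


@lru_cache(maxsize=200_000)
def _shapiro_distance_cached(db_a: str, db_b: str) -> int:
    from .structures import parse_dotbracket

    return tree_edit_distance(
        shapiro_tree(parse_dotbracket(db_a)), shapiro_tree(parse_dotbracket(db_b))
    )


def shapiro_distance(sa: SecondaryStructure, sb: SecondaryStructure) -> int:
    """Tree edit distance between the coarse-grained trees of two structures.

    Memoized on the dot-bracket strings: annealing re-evaluates the same
    candidate structures against a fixed target constantly.
    """
    return _shapiro_distance_cached(sa.dotbracket, sb.dotbracket)
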