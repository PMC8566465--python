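"""Rooted phylogenies: Newick I/O, pruning, MRCA and distance queries.

Trees are rooted, carry branch lengths in millions of years (Myr), and may
contain polytomies (consensus trees often do).  Zero-length branches are
legal.  All traversals are iterative so deep (caterpillar-like) trees do not
hit the interpreter recursion limit.
"""

from __future__ import annotations

import math
import re
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Node",
    "Phylogeny",
    "NewickError",
    "parse_newick",
    "write_newick",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character position of the offending token."""

    def __init__(self, message: str, position: Optional[int] = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class Node:
    """A node in a rooted tree.

    ``length`` is the length of the branch connecting the node to its parent
    (``None`` only for the root).  ``comment`` holds a bracketed Newick
    comment verbatim; annotated output (e.g. ancestral posteriors) is written
    through it.
    """

    __slots__ = ("label", "length", "comment", "parent", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None,
                 comment: Optional[str] = None):
        self.label = label
        self.length = length
        self.comment = comment
        self.parent: Optional[Node] = None
        self.children: List[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Phylogeny:
    """A validated rooted tree with uniquely labelled tips."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # ------------------------------------------------------------------ basics
    def _validate(self) -> None:
        seen: set = set()
        labels: set = set()
        for node in self.preorder():
            if id(node) in seen:
                raise ValueError("tree contains a cycle or shared node")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("inconsistent parent link")
            if node is not self.root:
                if node.length is None:
                    raise ValueError(f"non-root node {node.label!r} lacks a branch length")
                if not math.isfinite(node.length) or node.length < 0:
                    raise ValueError(
                        f"branch length of node {node.label!r} must be finite and >= 0, "
                        f"got {node.length!r}")
            if node.is_leaf:
                if not node.label:
                    raise ValueError("tip with empty label")
                if node.label in labels:
                    raise ValueError(f"duplicate tip label {node.label!r}")
                labels.add(node.label)
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")

    def preorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> List[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def __len__(self) -> int:
        return len(self.preorder())

    def node_depths(self) -> Dict[int, float]:
        """Map ``id(node)`` -> distance from the root (root = 0)."""
        depths: Dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    @property
    def height(self) -> float:
        depths = self.node_depths()
        return max(depths[id(t)] for t in self.tips())

    @property
    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    def node_ids(self) -> Dict[int, str]:
        """Stable node identifiers: tips keep their labels, internal nodes are
        numbered ``N0, N1, ...`` in preorder."""
        ids: Dict[int, str] = {}
        j = 0
        for node in self.preorder():
            if node.is_leaf:
                ids[id(node)] = node.label
            else:
                ids[id(node)] = f"N{j}"
                j += 1
        return ids

    def copy(self) -> "Phylogeny":
        mapping: Dict[int, Node] = {}
        for node in self.preorder():
            clone = Node(node.label, node.length, node.comment)
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return Phylogeny(mapping[id(self.root)], validate=False)

    # ------------------------------------------------------------------ queries
    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.node_depths()
        tipd = [depths[id(t)] for t in self.tips()]
        dmax = max(tipd)
        if dmax == 0:
            return True
        return all(abs(d - dmax) <= rel_tol * dmax for d in tipd)

    def _tip_map(self) -> Dict[str, Node]:
        return {t.label: t for t in self.tips()}

    def mrca(self, taxa: Iterable[str]) -> Node:
        """Most recent common ancestor of a non-empty set of tip labels."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("mrca of an empty taxon set is undefined")
        tip_map = self._tip_map()
        unknown = sorted(taxa - tip_map.keys())
        if unknown:
            raise KeyError(f"unknown taxa: {', '.join(unknown)}")
        targets = {id(tip_map[t]) for t in taxa}
        need = len(targets)
        counts: Dict[int, int] = {}
        for node in self.postorder():
            c = 1 if id(node) in targets else 0
            for child in node.children:
                c += counts[id(child)]
            counts[id(node)] = c
            if c == need:
                return node
        raise RuntimeError("unreachable: root must contain all tips")

    def prune_to_taxa(self, taxa: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``taxa``; collapse unary nodes, summing lengths.

        Patristic distances among the retained tips are preserved exactly
        (up to float addition).
        """
        taxa = set(taxa)
        tip_map = self._tip_map()
        unknown = sorted(taxa - tip_map.keys())
        if unknown:
            raise KeyError(f"unknown taxa: {', '.join(unknown)}")
        if len(taxa) < 2:
            raise ValueError("pruning requires at least 2 retained taxa")
        kept: Dict[int, Optional[Node]] = {}
        for node in self.postorder():
            if node.is_leaf:
                kept[id(node)] = (Node(node.label, node.length, node.comment)
                                  if node.label in taxa else None)
                continue
            kids = [kept[id(c)] for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                kept[id(node)] = None
            elif len(kids) == 1:
                # unary node created by pruning: collapse into the child
                child = kids[0]
                if node.length is not None:
                    child.length = (child.length or 0.0) + node.length
                kept[id(node)] = child
            else:
                clone = Node(node.label, node.length, node.comment)
                for k in kids:
                    clone.add_child(k)
                kept[id(node)] = clone
        new_root = kept[id(self.root)]
        assert new_root is not None
        new_root.length = None
        new_root.parent = None
        return Phylogeny(new_root)

    def patristic_matrix(self, order: Optional[Sequence[str]] = None
                         ) -> Tuple[List[str], np.ndarray]:
        """Pairwise tip-to-tip path-length matrix.

        Returns ``(labels, D)`` with ``D[i, j]`` the patristic distance between
        ``labels[i]`` and ``labels[j]``; ``order`` fixes the label order
        (default: tree tip order).
        """
        tips = self.tips()
        labels = [t.label for t in tips]
        index = {lbl: i for i, lbl in enumerate(labels)}
        depths = self.node_depths()
        tipdep = np.array([depths[id(t)] for t in tips])
        n = len(tips)
        D = np.zeros((n, n))
        below: Dict[int, np.ndarray] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = np.array([index[node.label]], dtype=np.intp)
                continue
            groups = [below.pop(id(c)) for c in node.children]
            dv = depths[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ga, gb = groups[a], groups[b]
                    block = (tipdep[ga][:, None] + tipdep[gb][None, :]) - 2.0 * dv
                    D[np.ix_(ga, gb)] = block
                    D[np.ix_(gb, ga)] = block.T
            below[id(node)] = np.concatenate(groups)
        if order is not None:
            order = list(order)
            missing = sorted(set(order) - set(labels))
            if missing:
                raise KeyError(f"unknown taxa: {', '.join(missing)}")
            perm = np.array([index[lbl] for lbl in order], dtype=np.intp)
            return order, D[np.ix_(perm, perm)]
        return labels, D

    # ------------------------------------------------------------------ I/O
    def write(self) -> str:
        return write_newick(self)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_BARE_DELIMS = set("(),:;[]'")
_NEEDS_QUOTING = set("(),:;[]' \t\n")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree.

    Accepts plain or single-quoted labels, bracketed comments (preserved
    verbatim on the node) and polytomies.  Raises :class:`NewickError` with
    the offending character position for malformed input, including duplicate
    or empty tip labels and negative branch lengths.
    """
    i, n = 0, len(text)
    root = Node()
    node = root
    stack: List[Node] = []
    label_pos: Dict[int, int] = {}
    finished = False
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif finished:
            raise NewickError("trailing characters after ';'", i)
        elif c == "(":
            child = Node()
            node.add_child(child)
            stack.append(node)
            node = child
            i += 1
        elif c == ",":
            if not stack:
                raise NewickError("comma outside parentheses", i)
            sibling = Node()
            stack[-1].add_child(sibling)
            node = sibling
            i += 1
        elif c == ")":
            if not stack:
                raise NewickError("unbalanced ')'", i)
            node = stack.pop()
            i += 1
        elif c == ";":
            if stack:
                raise NewickError("unbalanced '(': ';' before all groups closed", i)
            finished = True
            i += 1
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise NewickError("unterminated comment '['", i)
            node.comment = text[i + 1:j]
            i = j + 1
        elif c == ":":
            m = _NUMBER_RE.match(text, i + 1)
            if m is None:
                raise NewickError("expected a branch length after ':'", i + 1)
            length = float(m.group())
            if length < 0:
                raise NewickError(f"negative branch length {m.group()}", i + 1)
            node.length = length
            i = m.end()
        elif c == "'":
            j = i + 1
            pieces: List[str] = []
            while True:
                k = text.find("'", j)
                if k < 0:
                    raise NewickError("unterminated quoted label", i)
                pieces.append(text[j:k])
                if k + 1 < n and text[k + 1] == "'":  # escaped quote
                    pieces.append("'")
                    j = k + 2
                else:
                    j = k + 1
                    break
            node.label = "".join(pieces)
            label_pos[id(node)] = i
            i = j
        else:
            j = i
            while j < n and text[j] not in _BARE_DELIMS and not text[j].isspace():
                j += 1
            if j == i:
                raise NewickError(f"unexpected character {c!r}", i)
            node.label = text[i:j]
            label_pos[id(node)] = i
            i = j
    if stack:
        raise NewickError("unbalanced '(': input ended before all groups closed", n)
    if not finished:
        raise NewickError("missing terminating ';'", n)
    # tip-label checks with positions
    seen: Dict[str, int] = {}
    probe = Phylogeny(root, validate=False)
    for tip in probe.tips():
        if not tip.label:
            raise NewickError("tip without a label", label_pos.get(id(tip)))
        if tip.label in seen:
            raise NewickError(f"duplicate tip label {tip.label!r}",
                              label_pos.get(id(tip)))
        seen[tip.label] = label_pos.get(id(tip), -1)
    tree = Phylogeny(root)
    return tree


def _format_length(x: float) -> str:
    # repr() is the shortest round-tripping decimal form: parse(write(T))
    # reproduces lengths exactly.
    return repr(float(x))


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny) -> str:
    rendered: Dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(rendered.pop(id(c)) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if node.comment is not None:
            s += "[" + node.comment + "]"
        if node.length is not None and node is not tree.root:
            s += ":" + _format_length(node.length)
        rendered[id(node)] = s
    return rendered[id(tree.root)] + ";"
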