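"""Rooted time trees, Newick I/O, MRP supertree search and time calibration.

The tree container is deliberately small: rooted topology with polytomies,
node ages in Ma before present and branch lengths in My, plus named clade
annotations (tip sets).  Newick parsing and serialization are delegated to
dendropy; parsimony search (Fitch length, exhaustive enumeration and NNI
hill-climbing) operates directly on this structure.
"""

from __future__ import annotations

import dataclasses
import itertools
import random
import warnings
from typing import Iterable, Iterator

import numpy as np
import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "age", "children", "parent", "id")

    def __init__(self, label: str | None = None,
                 length: float | None = None) -> None:
        self.label = label
        self.length = length
        self.age: float | None = None
        self.children: list["Node"] = []
        self.parent: "Node" | None = None
        self.id: int = -1

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or self.id}>"


@dataclasses.dataclass
class TimeTree:
    """Rooted, optionally time-calibrated phylogeny."""

    root: Node
    clades: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index()
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    def _index(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.id = i

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def nodes(self) -> list[Node]:
        return list(self.preorder())

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def tip(self, label: str) -> Node:
        for n in self.tips:
            if n.label == label:
                return n
        raise TreeError(f"tip {label!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        best: Node | None = None
        for node in self.postorder():
            below = {t.label for t in _subtree_tips(node)}
            if want <= below:
                if best is None or len(below) < len(
                        {t.label for t in _subtree_tips(best)}):
                    best = node
        assert best is not None
        return best

    def clade_node(self, name: str) -> Node:
        if name not in self.clades:
            raise TreeError(f"clade {name!r} not annotated on tree")
        return self.mrca(self.clades[name])

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (branch lengths must be set)."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(f"node {node.label or node.id} has no branch length")
            out[node.id] = out[node.parent.id] + node.length
        return out

    def copy(self) -> "TimeTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.length)
            clone.age = node.age
            for ch in node.children:
                clone.add(rec(ch))
            return clone
        return TimeTree(rec(self.root), dict(self.clades))


def _subtree_tips(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)

def read_newick(text: str) -> TimeTree:
    """Parse a Newick string into a TimeTree (topology + optional lengths)."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc

    def rec(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for ch in dnode.child_nodes():
            node.add(rec(ch))
        return node

    return TimeTree(rec(dtree.seed_node))


def write_newick(tree: TimeTree) -> str:
    """Serialize topology, labels and branch lengths to Newick."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if node.length is not None:
            s += f":{node.length:.10g}"
        return s

    return rec(tree.root) + ";"


def read_tip_ages(path) -> dict[str, float]:
    """Tip-age CSV (taxon, age_Ma) -> mapping."""
    import pandas as pd
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def read_clades(path) -> dict[str, frozenset[str]]:
    """Clade-annotation CSV (clade, taxon) -> named tip sets."""
    import pandas as pd
    df = pd.read_csv(path)
    out: dict[str, set[str]] = {}
    for clade, taxon in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(clade, set()).add(taxon)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# MRP supertree

@dataclasses.dataclass
class MRPMatrix:
    """Baum-Ragan binary incidence matrix with missing entries.

    ``matrix`` is (taxa x characters) int8 with 1 = clade member,
    0 = sampled non-member, -1 = taxon absent from the source tree.
    """

    taxa: list[str]
    matrix: np.ndarray
    provenance: list[int]

    @property
    def n_characters(self) -> int:
        return self.matrix.shape[1]


def mrp_encode(source_trees: list[TimeTree]) -> MRPMatrix:
    """One binary character per non-trivial clade per source tree."""
    if not source_trees:
        raise TreeError("no source trees")
    usable = []
    for i, t in enumerate(source_trees):
        if len(t.tips) < 3:
            warnings.warn(f"source tree {i} has < 3 tips; skipped",
                          stacklevel=2)
            continue
        usable.append((i, t))
    if not usable:
        raise TreeError("no usable source trees (all < 3 tips)")
    taxa = sorted({l for _, t in usable for l in t.tip_labels})
    tindex = {l: j for j, l in enumerate(taxa)}
    cols, prov = [], []
    for i, t in usable:
        sampled = set(t.tip_labels)
        all_tips = frozenset(sampled)
        for node in t.postorder():
            if node.is_leaf or node is t.root:
                continue
            members = frozenset(x.label for x in _subtree_tips(node))
            if len(members) < 2 or members == all_tips:
                continue
            col = np.full(len(taxa), -1, dtype=np.int8)
            for l in sampled:
                col[tindex[l]] = 1 if l in members else 0
            cols.append(col)
            prov.append(i)
    if not cols:
        raise TreeError("source trees contain no non-trivial clades")
    return MRPMatrix(taxa=taxa, matrix=np.column_stack(cols), provenance=prov)


# -- parsimony machinery -----------------------------------------------------
# A candidate topology is held as nested tuples over taxon indices; the
# hypothetical all-zero outgroup roots the tree, so Fitch length is computed
# on the rooted shape with state sets as bitmasks (1=state0, 2=state1, 3=?).


def _fitch_length(topo, states: np.ndarray, root_zero: bool = False) -> int:
    """Fitch parsimony length summed over characters (vectorised).

    ``states`` is (taxa, chars) int8 in {0, 1, -1} (missing = wildcard).
    With ``root_zero`` an all-zero hypothetical ancestor is attached at the
    top-level node (one extra step per character whose root state set
    excludes 0).
    """
    n_char = states.shape[1]
    masks = np.empty((states.shape[0], n_char), dtype=np.int8)
    masks[states == 0] = 1
    masks[states == 1] = 2
    masks[states == -1] = 3
    total = np.zeros(n_char, dtype=np.int64)

    def rec(node) -> np.ndarray:
        if isinstance(node, int):
            return masks[node]
        sets = [rec(ch) for ch in node]
        inter = sets[0].copy()
        union = sets[0].copy()
        for s in sets[1:]:
            inter &= s
            union |= s
        empty = inter == 0
        total[empty] += 1
        out = inter
        out[empty] = union[empty]
        return out

    root_set = rec(topo)
    if root_zero:
        total[(root_set & 1) == 0] += 1
    return int(total.sum())


def _insert_on_edges(topo, leaf) -> list:
    """Variants of a trifurcating-root topology with ``leaf`` grafted onto
    each of its 2n-3 edges (the edge above every non-root node)."""

    def rec(node) -> list:
        if isinstance(node, int):
            return []
        variants = []
        for i, child in enumerate(node):
            grafted = tuple((child, leaf) if j == i else c
                            for j, c in enumerate(node))
            variants.append(grafted)
            for sub in rec(child):
                variants.append(tuple(sub if j == i else c
                                      for j, c in enumerate(node)))
        return variants

    return rec(topo)


def _enumerate_topologies(n: int) -> Iterator:
    """All unrooted binary topologies on taxa 0..n-1 (trifurcating-root form)
    via sequential edge addition."""
    if n < 3:
        raise TreeError("need >= 3 taxa to enumerate topologies")
    trees = [(0, 1, 2)]
    for leaf in range(3, n):
        trees = [t for base in trees for t in _insert_on_edges(base, leaf)]
    return iter(trees)


def _topo_clades(topo, n: int, outgroup: int | None = None
                 ) -> set[frozenset[int]]:
    """Non-trivial clades of a topology.

    With ``outgroup`` given, splits are read relative to the rooting at
    that leaf: for every edge the side not containing the outgroup is the
    clade, and the outgroup itself is dropped from the universe.
    """
    out: set[frozenset[int]] = set()
    universe = frozenset(range(n)) - (
        frozenset() if outgroup is None else frozenset([outgroup]))

    def rec(node) -> frozenset[int]:
        if isinstance(node, int):
            return frozenset([node])
        s = frozenset().union(*(rec(c) for c in node))
        clade = s if (outgroup is None or outgroup not in s) \
            else universe - (s - {outgroup})
        if 1 < len(clade) < len(universe):
            out.add(clade)
        return s

    rec(topo)
    return out


def _tree_from_clades(clades: set[frozenset[int]], taxa: list[str]) -> TimeTree:
    """Build a rooted TimeTree from a nested (strict-consensus) clade set."""
    n = len(taxa)
    items = sorted(clades, key=len, reverse=True)
    root = Node()
    node_of: dict[frozenset[int], Node] = {frozenset(range(n)): root}
    parents = [frozenset(range(n))] + items
    for clade in items:
        parent = min((p for p in node_of if clade < p), key=len)
        node_of[clade] = node_of[parent].add(Node())
        parents.append(clade)
    for i, label in enumerate(taxa):
        parent = min((p for p in node_of if i in p), key=len)
        node_of[parent].add(Node(label=label))
    return TimeTree(root)


def _random_topology(n: int, rng: random.Random):
    topo = (0, 1, 2)
    for leaf in range(3, n):
        topo = rng.choice(_insert_on_edges(topo, leaf))
    return topo


def _nni_neighbors(topo):
    """All NNI rearrangements of a nested-tuple topology."""
    results = []

    def rec(node, rebuild):
        if isinstance(node, int):
            return
        for i, child in enumerate(node):
            if isinstance(child, tuple):
                # swap one grandchild with one sibling subtree
                for j, sib in enumerate(node):
                    if j == i:
                        continue
                    for gi, grand in enumerate(child):
                        new_child = tuple(sib if g == gi else c
                                          for g, c in enumerate(child))
                        new_node = tuple(
                            new_child if k == i else (grand if k == j else c)
                            for k, c in enumerate(node))
                        results.append(rebuild(new_node))
            rec(child, lambda sub, i=i, node=node, rebuild=rebuild: rebuild(
                tuple(sub if k == i else c for k, c in enumerate(node))))

    rec(topo, lambda x: x)
    return results


def _spr_neighbors(topo):
    """Subtree-prune-regraft rearrangements of a nested-tuple topology."""
    pairs = []

    def prune(node, rebuild):
        if isinstance(node, int):
            return
        for i, child in enumerate(node):
            rest = tuple(c for j, c in enumerate(node) if j != i)
            remaining = rebuild(rest[0] if len(rest) == 1 else rest)
            pairs.append((child, remaining))
            prune(child, lambda sub, i=i, node=node, rebuild=rebuild:
                  rebuild(tuple(sub if j == i else c
                                for j, c in enumerate(node))))

    prune(topo, lambda x: x)
    results = []
    for sub, remaining in pairs:
        if isinstance(remaining, int):
            continue
        results.extend(_insert_on_edges(remaining, sub))
    return results


def _hillclimb(topo, states):
    score = _fitch_length(topo, states)
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(topo):
            s = _fitch_length(nb, states)
            if s < score:
                topo, score = nb, s
                improved = True
                break
        if not improved:
            for nb in _spr_neighbors(topo):
                s = _fitch_length(nb, states)
                if s < score:
                    topo, score = nb, s
                    improved = True
                    break
    return topo, score


def mrp_supertree(matrix: MRPMatrix, search: str = "hillclimb",
                  seed: int = 0, n_restarts: int = 10,
                  max_exhaustive: int = 9,
                  with_score: bool = False) -> TimeTree:
    """Most-parsimonious supertree from an MRP matrix.

    ``exhaustive`` enumerates every unrooted topology (allowed for <= 9
    taxa); ``hillclimb`` runs NNI hill-climbing from seeded random starting
    trees.  Ties among equally parsimonious topologies are broken by strict
    consensus.  With ``with_score`` the best Fitch length found is returned
    alongside the tree.
    """
    taxa = matrix.taxa
    n = len(taxa)
    if n < 4:
        raise TreeError("supertree needs >= 4 taxa")
    _check_overlap(matrix)
    # the all-zero hypothetical ancestor is an explicit leaf (index n): its
    # attachment point is part of the search, and it roots the result
    og = n
    n_all = n + 1
    states = np.vstack([matrix.matrix,
                        np.zeros((1, matrix.n_characters), dtype=np.int8)])

    if search == "exhaustive":
        if n > max_exhaustive:
            raise TreeError(
                f"exhaustive search limited to {max_exhaustive} taxa, got {n}")
        best, best_score = [], None
        for topo in _enumerate_topologies(n_all):
            score = _fitch_length(topo, states)
            if best_score is None or score < best_score:
                best, best_score = [topo], score
            elif score == best_score:
                best.append(topo)
    elif search == "hillclimb":
        rng = random.Random(seed)
        best, best_score = [], None
        best_splits: list[set[frozenset[int]]] = []
        for _ in range(n_restarts):
            topo, score = _hillclimb(_random_topology(n_all, rng), states)
            splits = _topo_clades(topo, n_all, outgroup=og)
            if best_score is None or score < best_score:
                best, best_score, best_splits = [topo], score, [splits]
            elif score == best_score and splits not in best_splits:
                best.append(topo)
                best_splits.append(splits)
    else:
        raise TreeError(f"unknown search strategy {search!r}")

    clade_sets = [_topo_clades(t, n_all, outgroup=og) for t in best]
    consensus = set.intersection(*clade_sets) if clade_sets else set()
    tree = _tree_from_clades(consensus, taxa)
    if with_score:
        return tree, best_score
    return tree


def parsimony_length(matrix: MRPMatrix, tree: TimeTree) -> int:
    """Fitch length of a rooted supertree on the matrix (all-zero ancestor
    attached at the root)."""
    tindex = {l: i for i, l in enumerate(matrix.taxa)}

    def to_tuple(node: Node):
        if node.is_leaf:
            return tindex[node.label]
        return tuple(to_tuple(c) for c in node.children)

    return _fitch_length(to_tuple(tree.root), matrix.matrix, root_zero=True)


def _check_overlap(matrix: MRPMatrix) -> None:
    """Source trees must form a connected taxon-overlap graph."""
    groups: dict[int, set[str]] = {}
    for j, src in enumerate(matrix.provenance):
        scored = {matrix.taxa[i] for i in
                  np.nonzero(matrix.matrix[:, j] >= 0)[0]}
        groups.setdefault(src, set()).update(scored)
    comps = [set(g) for g in groups.values()]
    merged = True
    while merged and len(comps) > 1:
        merged = False
        for a, b in itertools.combinations(range(len(comps)), 2):
            if comps[a] & comps[b]:
                comps[a] |= comps.pop(b)
                merged = True
                break
    if len(comps) > 1:
        raise TreeError("supertree undefined: disconnected taxon overlap")


# ---------------------------------------------------------------------------
# Time calibration

def time_calibrate(topology: TimeTree, tip_ages: dict[str, float],
                   mbl: float = 1.0) -> TimeTree:
    """Conservative (minimal) node ages from tip ages.

    Postorder: each node's age is the maximum over children of
    (child age + mbl), i.e. every branch is at least ``mbl`` My long and no
    node is older than it has to be.  Branch lengths are set to parent age
    minus child age.
    """
    if mbl <= 0:
        raise TreeError("mbl must be > 0")
    tree = topology.copy()
    missing = [l for l in tree.tip_labels if l not in tip_ages]
    if missing:
        raise TreeError(f"missing tip ages for: {missing}")
    for node in tree.postorder():
        if node.is_leaf:
            node.age = float(tip_ages[node.label])
        else:
            node.age = max(c.age + mbl for c in node.children)
    for node in tree.preorder():
        if node is tree.root:
            node.length = None
        else:
            node.length = node.parent.age - node.age
    return tree
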