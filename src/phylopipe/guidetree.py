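"""Distance-based guide trees and iterative in-group paralog collapse.

In-group paralogs — multiple sequences from one taxon that form a
monophyletic group on a quick guide tree — represent recent gene
duplications.  They add little signal at deep timescales and inflate
computational cost, so all but one representative are removed.  Because
the guide tree is fast and approximate, the collapse is iterated: each
round rebuilds a p-distance matrix and a neighbor-joining tree from the
survivors, until no same-taxon clade remains or ``max_iter`` is hit.

Monophyly is evaluated in the bipartition sense on the unrooted
topology: a leaf set is monophyletic iff removing a single edge isolates
exactly that set.  This avoids any dependence on root placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import dendropy
import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .naming import taxon_prefix
from .pairwise import AlignmentParams, DEFAULT_AA, global_align
from .seqio import read_newick

Record = tuple[str, str]

__all__ = [
    "DistanceMatrix",
    "pdistance_matrix",
    "alignment_pdistance",
    "nj_tree",
    "bipartition_sides",
    "is_monophyletic",
    "collapse_ingroup_paralogs",
]


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("duplicate leaf names in distance matrix")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} names")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and nonnegative")
        self.values = v

    def __len__(self) -> int:
        return len(self.names)


def pdistance_matrix(
    records: Sequence[Record],
    params: AlignmentParams = DEFAULT_AA,
    max_distance: float = 1.0,
) -> DistanceMatrix:
    """Pairwise p-distances (1 − identity fraction over the overlap) from
    global alignments of unaligned records.  Pairs with zero overlap get
    ``max_distance``."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    names = [name for name, _ in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i][1], records[j][1], params)
            dist = max_distance if res.overlap_len == 0 else 1.0 - res.identity_pct / 100.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(names, d)


def alignment_pdistance(
    names: Sequence[str],
    rows: Sequence[str],
    max_distance: float = 1.0,
) -> DistanceMatrix:
    """p-distances straight from aligned rows (columns where both rows
    hold residues); pairs sharing no column get ``max_distance``."""
    n = len(names)
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            total = int(both.sum())
            if total == 0:
                dist = max_distance
            else:
                dist = 1.0 - float((arr[i][both] == arr[j][both]).sum()) / total
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(names), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree (negative branch lengths clamped)."""
    if len(dm) < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    skdm = skbio.DistanceMatrix(dm.values, ids=dm.names)
    tree = _skbio_nj(skdm)
    buf = StringIO()
    tree.write(buf, format="newick")
    out = read_newick(buf.getvalue(), is_path=False)
    out.is_rooted = False
    return out


# ---------------------------------------------------------------------------
# bipartitions / monophyly


def bipartition_sides(tree: dendropy.Tree) -> list[tuple[frozenset, dendropy.Edge]]:
    """Every bipartition side of the tree as (leaf-label set, edge).

    For each edge the set of leaves on the child side is returned; the
    complement side is implied.  Pendant edges are included."""
    sides: list[tuple[frozenset, dendropy.Edge]] = []
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            sides.append((below[node], node.edge))
    return sides


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def is_monophyletic(tree: dendropy.Tree, labels: frozenset | set) -> bool:
    """Bipartition-sense monophyly on the unrooted topology."""
    labels = frozenset(labels)
    all_leaves = leaf_labels(tree)
    if not labels or not labels.issubset(all_leaves):
        return False
    if len(labels) in (1, len(all_leaves)):
        return True
    for side, _edge in bipartition_sides(tree):
        if side == labels or (all_leaves - side) == labels:
            return True
    return False


# ---------------------------------------------------------------------------
# in-group paralog collapse


@dataclass
class CollapseRemoval:
    name: str
    taxon: str
    representative: str
    iteration: int


def _same_taxon_monophyletic_groups(tree: dendropy.Tree) -> list[frozenset]:
    """Maximal same-taxon leaf sets (size >= 2) isolated by a single edge."""
    all_leaves = leaf_labels(tree)
    candidates: set[frozenset] = set()
    for side, _edge in bipartition_sides(tree):
        for group in (side, all_leaves - side):
            if len(group) < 2 or len(group) == len(all_leaves):
                continue
            prefixes = {taxon_prefix(name) for name in group}
            if len(prefixes) == 1:
                candidates.add(group)
    maximal = [g for g in candidates if not any(g < other for other in candidates)]
    return sorted(maximal, key=lambda g: sorted(g))


def collapse_ingroup_paralogs(
    records: Sequence[Record],
    max_iter: int = 5,
    params: AlignmentParams = DEFAULT_AA,
    guide_tree: dendropy.Tree | None = None,
) -> tuple[list[Record], list[CollapseRemoval], int]:
    """Iteratively remove all but one representative of every same-taxon
    monophyletic group on the guide tree.

    The kept representative is the longest unaligned sequence (name
    order breaks ties).  An externally computed guide tree may be passed
    for the first iteration; later iterations always rebuild p-distance
    NJ trees from the survivors.  Fewer than 3 records are returned
    unchanged (no tree is possible).
    """
    current = list(records)
    removed: list[CollapseRemoval] = []
    iterations = 0
    for it in range(1, max_iter + 1):
        if len(current) < 3:
            break
        iterations = it
        if guide_tree is not None and it == 1:
            tree = guide_tree
        else:
            tree = nj_tree(pdistance_matrix(current, params))
        groups = _same_taxon_monophyletic_groups(tree)
        if not groups:
            break
        seqs = dict(current)
        to_remove: set[str] = set()
        for group in groups:
            members = sorted(group, key=lambda n: (-len(seqs[n]), n))
            rep = members[0]
            for name in members[1:]:
                to_remove.add(name)
                removed.append(CollapseRemoval(name, taxon_prefix(name), rep, it))
        current = [(n, s) for n, s in current if n not in to_remove]
    return current, removed, iterations
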