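"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration or a separate
recursion, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache


def needle_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score with affine gaps and free terminal
    gaps, by memoized recursion over (position, position, state).

    States: 0 = last column was a substitution (or start), 1 = last
    column gapped sequence b, 2 = last column gapped sequence a.
    A gap of length k costs gap_open + (k-1) * gap_extend; leading and
    trailing gaps are free.
    """
    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # best score of aligning a[i:], b[j:] given the previous column state
        if i == la and j == lb:
            return 0.0
        if i == la:  # trailing gap in a: free
            return 0.0
        if j == lb:  # trailing gap in b: free
            return 0.0
        options = []
        options.append(matrix[a[i], b[j]] + best(i + 1, j + 1, 0))
        cost_open_b = gap_extend if state == 1 else gap_open
        options.append(-cost_open_b + best(i + 1, j, 1))
        cost_open_a = gap_extend if state == 2 else gap_open
        options.append(-cost_open_a + best(i, j + 1, 2))
        return max(options)

    # leading free gaps: start anywhere on the first row/column
    candidates = [best(0, 0, 0)]
    for i in range(1, la + 1):
        candidates.append(best(i, 0, 0))
    for j in range(1, lb + 1):
        candidates.append(best(0, j, 0))
    return max(candidates)


def pure_clade_sizes(adjacency: dict, leaf_clade: dict, leaf: str) -> int:
    """Largest edge-defined leaf set containing ``leaf`` whose members
    all share its clade, by enumerating every edge cut of the tree graph."""
    nodes = set(adjacency)
    best = 1
    for u in adjacency:
        for v in adjacency[u]:
            if u >= v:
                continue
            side = _reachable(adjacency, u, v)
            for s in (side, nodes - side):
                leaves = {n for n in s if n in leaf_clade}
                if leaf in leaves and len(leaves) < len(leaf_clade):
                    if all(leaf_clade[m] == leaf_clade[leaf] for m in leaves):
                        best = max(best, len(leaves))
    return best


def _reachable(adjacency: dict, start, blocked) -> set:
    seen = {start, blocked}
    stack = [start]
    while stack:
        n = stack.pop()
        for nb in adjacency[n]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(blocked)
    return seen


def tree_adjacency(tree) -> tuple[dict, dict]:
    """Adjacency over node ids plus leaf id -> label, built by direct
    parent/child traversal (independent of the package helpers)."""
    adjacency: dict = {}
    labels: dict = {}
    for node in tree.preorder_node_iter():
        adjacency.setdefault(id(node), set())
        if node.is_leaf():
            labels[id(node)] = node.taxon.label
        for child in node.child_nodes():
            adjacency[id(node)].add(id(child))
            adjacency.setdefault(id(child), set()).add(id(node))
    return adjacency, labels


def nearest_leaves_by_bfs(tree, leaf_label: str, min_neighbors: int) -> set:
    """Nearest other leaves by edge distance, radius grown until at
    least ``min_neighbors`` collected (ties included)."""
    adjacency, labels = tree_adjacency(tree)
    start = next(i for i, l in labels.items() if l == leaf_label)
    dist = {start: 0}
    order: list[tuple[int, str]] = []
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for n in frontier:
            for nb in adjacency[n]:
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
                    if nb in labels:
                        order.append((d, labels[nb]))
        frontier = nxt
    pool: set = set()
    last_d = None
    for d, label in sorted(order):
        if len(pool) >= min_neighbors and d != last_d:
            break
        pool.add(label)
        last_d = d
    return pool


def pair_support_scores(base_names, base_rows, alt_alignments, n_alts):
    """Column and sequence support by direct per-pair enumeration."""
    n = len(base_names)
    L = len(base_rows[0])

    def residue_cols(rows):
        out = []
        for row in rows:
            cols = {}
            k = 0
            for c, ch in enumerate(row):
                if ch != "-":
                    cols[k] = c
                    k += 1
            out.append(cols)
        return out

    def residue_index(rows):
        out = []
        for row in rows:
            idx = []
            k = 0
            for ch in row:
                if ch == "-":
                    idx.append(None)
                else:
                    idx.append(k)
                    k += 1
            out.append(idx)
        return out

    base_idx = residue_index(base_rows)
    alt_maps = []
    for names, rows in alt_alignments:
        order = [names.index(nm) for nm in base_names]
        alt_maps.append(residue_cols([rows[k] for k in order]))

    col_scores = []
    seq_support: dict[str, list[float]] = {nm: [] for nm in base_names}
    for c in range(L):
        supports = []
        for i in range(n):
            for j in range(i + 1, n):
                ri, rj = base_idx[i][c], base_idx[j][c]
                if ri is None or rj is None:
                    continue
                agree = sum(
                    1 for m in alt_maps if m[i].get(ri) == m[j].get(rj) and m[i].get(ri) is not None
                )
                s = agree / n_alts
                supports.append(s)
                seq_support[base_names[i]].append(s)
                seq_support[base_names[j]].append(s)
        col_scores.append(sum(supports) / len(supports) if supports else 1.0)
    seq_scores = {
        nm: (sum(v) / len(v) if v else 1.0) for nm, v in seq_support.items()
    }
    return col_scores, seq_scores
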