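"""Cross-domain contaminant screening on gene trees.

Misidentified sequences — environmental contaminants, food-source reads,
or very recent lateral transfers — show up on single-gene trees as lone
leaves nested deep inside a foreign domain: a putatively eukaryotic
sequence surrounded by bacteria, say.  Such singletons carry no vertical
phylogenetic signal and only add noise to a supermatrix, so they are
removed.  The strict naming standard makes the check purely label-based.

The nestedness rule: expand outward from the leaf ``L`` on the unrooted
topology, collecting other leaves in order of increasing edge distance,
and stop at the smallest radius that yields at least ``min_neighbors``
neighbors (ties at that radius are all included).  ``L`` is flagged iff
every leaf in that neighborhood belongs to one single domain different
from ``L``'s.  A same-domain leaf anywhere in the neighborhood vetoes
the flag, so pairs of related taxa sitting together in an unexpected
place are never removed.  Raising ``min_neighbors`` can only widen the
radius and hence grow the neighborhood, so the flagged set shrinks
monotonically as the evidence requirement rises.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .guidetree import leaf_labels
from .naming import DomainTable, DEFAULT_DOMAIN_TABLE, parse_name

Record = tuple[str, str]

__all__ = ["FlaggedLeaf", "ScreenReport", "find_misplaced_leaves", "remove_flagged"]


@dataclass
class FlaggedLeaf:
    name: str
    leaf_domain: str
    surrounding_domain: str
    neighborhood_size: int


@dataclass
class ScreenReport:
    flagged: list[FlaggedLeaf] = field(default_factory=list)

    @property
    def flagged_names(self) -> set[str]:
        return {f.name for f in self.flagged}

    def tally_by_clade(self) -> dict[str, int]:
        """Removal counts grouped by major clade code."""
        return dict(Counter(parse_name(f.name).code.major_clade for f in self.flagged))

    def write_tsv(self, path: str | Path) -> None:
        lines = ["leaf\tleaf_domain\tsurrounding_domain\tneighborhood_size"]
        for f in self.flagged:
            lines.append(f"{f.name}\t{f.leaf_domain}\t{f.surrounding_domain}\t{f.neighborhood_size}")
        Path(path).write_text("\n".join(lines) + "\n")


def _group_key(name: str, domains: DomainTable, level: str) -> str:
    code = parse_name(name).code
    if level == "domain":
        return domains.domain(code.major_clade)
    return code.major_clade


def find_misplaced_leaves(
    tree: dendropy.Tree,
    domains: DomainTable = DEFAULT_DOMAIN_TABLE,
    min_neighbors: int = 3,
    level: str = "domain",
) -> ScreenReport:
    """Flag singleton leaves nested among foreign-domain leaves.

    ``level`` is ``"domain"`` (eukaryote vs bacteria vs archaea — the
    appropriate resolution for trees spanning all of life) or
    ``"clade"`` (major-clade codes; a stricter screen for studies of
    smaller time scales).
    """
    if level not in ("domain", "clade"):
        raise ValueError("level must be 'domain' or 'clade'")
    leaves = leaf_labels(tree)
    if len(leaves) < 4:
        return ScreenReport()
    group = {name: _group_key(name, domains, level) for name in leaves}

    adjacency, leaf_nodes = _adjacency(tree)
    report = ScreenReport()
    for name in sorted(leaves):
        pool = nearest_leaf_neighborhood(adjacency, leaf_nodes, name, min_neighbors)
        if len(pool) < min_neighbors:
            continue  # tree too small to provide the required evidence
        pool_groups = {group[m] for m in pool}
        if len(pool_groups) == 1 and pool_groups != {group[name]}:
            report.flagged.append(
                FlaggedLeaf(name, group[name], next(iter(pool_groups)), len(pool))
            )
    return report


def _adjacency(tree: dendropy.Tree):
    adjacency: dict[int, list[int]] = {}
    leaf_nodes: dict[str, int] = {}
    label: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        adjacency.setdefault(id(node), [])
        if node.is_leaf():
            leaf_nodes[node.taxon.label] = id(node)
            label[id(node)] = node.taxon.label
        for child in node.child_nodes():
            adjacency[id(node)].append(id(child))
            adjacency.setdefault(id(child), []).append(id(node))
    return (adjacency, label), leaf_nodes


def nearest_leaf_neighborhood(adjacency_info, leaf_nodes, name: str, min_neighbors: int) -> set[str]:
    """The nearest other leaves by edge distance: expand the BFS radius
    until at least ``min_neighbors`` leaves are collected, including all
    ties at the final radius."""
    adjacency, label = adjacency_info
    start = leaf_nodes[name]
    seen = {start}
    frontier = [start]
    pool: set[str] = set()
    while frontier:
        nxt = []
        ring: set[str] = set()
        for node in frontier:
            for nb in adjacency[node]:
                if nb in seen:
                    continue
                seen.add(nb)
                nxt.append(nb)
                if label.get(nb) is not None:
                    ring.add(label[nb])
        pool |= ring
        if len(pool) >= min_neighbors:
            break
        frontier = nxt
    return pool


def remove_flagged(
    records: Sequence[Record], report: ScreenReport
) -> tuple[list[Record], dict[str, int]]:
    """Drop flagged names from a record set; tally removals by major clade."""
    flagged = report.flagged_names
    names = {n for n, _ in records}
    missing = flagged - names
    if missing:
        raise ValueError(f"flagged names absent from input: {sorted(missing)}")
    kept = [(n, s) for n, s in records if n not in flagged]
    return kept, report.tally_by_clade()
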