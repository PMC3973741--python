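"""One-sequence-per-taxon ortholog selection for supermatrix building.

When a taxon retains several candidate sequences for a gene after
refinement (deep paralogy survives the earlier collapses), exactly one
may enter the concatenated matrix.  Single-gene trees at the scale of
all eukaryotes rarely resolve deep nodes well, so the choice leans on
local tree structure instead: keep the candidate with the largest
number of close neighbors from its own major clade, i.e. the one
sitting in the biggest clean clade of related taxa.  If *Arabidopsis*
has paralogs in a 5-Plantae clade, a 10-Plantae clade and inside a
fungal clade, the 10-Plantae copy is the ortholog to keep.

Ties — and taxa whose phylogenetic position is unknown ("orphan"
clades) — fall back to the shortest terminal branch; any remaining tie
breaks lexicographically so the choice is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .guidetree import bipartition_sides, leaf_labels
from .naming import parse_name

Record = tuple[str, str]

__all__ = ["CandidateScore", "SelectionDecision", "score_candidate", "select_orthologs"]


@dataclass
class CandidateScore:
    clade_size: int
    terminal_branch: float


@dataclass
class SelectionDecision:
    taxon: str
    kept: str
    discarded: list[str]
    scores: dict[str, CandidateScore]


def _clade_field(name: str, level: str) -> str:
    code = parse_name(name).code
    return code.major_clade if level == "major" else f"{code.major_clade}_{code.subclade}"


def score_candidate(
    tree: dendropy.Tree,
    leaf: str,
    level: str = "major",
) -> CandidateScore:
    """Score a candidate leaf by its clean-clade neighborhood.

    ``clade_size`` is the leaf count of the largest bipartition side
    containing the leaf whose members all share the leaf's major clade
    (the candidate itself and same-taxon co-candidates included; a
    single foreign member breaks the clade).  ``terminal_branch`` is the
    pendant edge length, 0 when lengths are absent.
    """
    leaves = leaf_labels(tree)
    if leaf not in leaves:
        raise ValueError(f"leaf {leaf!r} not in tree")
    my_clade = _clade_field(leaf, level)
    clade_of = {name: _clade_field(name, level) for name in leaves}

    best = 1  # the leaf alone is always a pure clade
    pendant = 0.0
    for node in tree.leaf_node_iter():
        if node.taxon.label == leaf and node.edge.length is not None:
            pendant = float(node.edge.length)
    for side, _edge in bipartition_sides(tree):
        for s in (side, leaves - side):
            if leaf not in s or len(s) == len(leaves):
                continue
            if all(clade_of[m] == my_clade for m in s):
                best = max(best, len(s))
    return CandidateScore(best, pendant)


def select_orthologs(
    tree: dendropy.Tree,
    records: Sequence[Record],
    orphan_clades: Iterable[str] = (),
    level: str = "major",
) -> tuple[list[Record], list[SelectionDecision]]:
    """Pick exactly one record per taxon using tree-neighborhood scores.

    For each taxon with several candidates keep the largest
    ``clade_size``; break ties by smallest terminal branch, then by
    name.  Taxa whose major clade is listed in ``orphan_clades`` are
    scored on terminal branch only.  Returns the one-per-taxon records
    (input order) and a decision log.
    """
    names = [n for n, _ in records]
    leaves = leaf_labels(tree)
    if set(names) != leaves:
        raise ValueError("record names do not match tree leaves")
    orphans = set(orphan_clades)

    by_taxon: dict[str, list[str]] = {}
    for name in names:
        by_taxon.setdefault(parse_name(name).code.prefix, []).append(name)

    keep: set[str] = set()
    log: list[SelectionDecision] = []
    for taxon, candidates in sorted(by_taxon.items()):
        if len(candidates) == 1:
            keep.add(candidates[0])
            continue
        scores = {c: score_candidate(tree, c, level) for c in candidates}
        is_orphan = parse_name(candidates[0]).code.major_clade in orphans

        def sort_key(c: str):
            s = scores[c]
            size = 0 if is_orphan else s.clade_size
            return (-size, s.terminal_branch, c)

        ranked = sorted(candidates, key=sort_key)
        keep.add(ranked[0])
        log.append(SelectionDecision(taxon, ranked[0], ranked[1:], scores))
    kept = [(n, s) for n, s in records if n in keep]
    return kept, log


def write_decision_log(log: Sequence[SelectionDecision], path: str | Path) -> None:
    lines = ["taxon\tkept\tcandidate\tclade_size\tterminal_branch\tdecision"]
    for d in log:
        for c, s in sorted(d.scores.items()):
            verdict = "kept" if c == d.kept else "discarded"
            lines.append(f"{d.taxon}\t{d.kept}\t{c}\t{s.clade_size}\t{s.terminal_branch:.6g}\t{verdict}")
    Path(path).write_text("\n".join(lines) + "\n")
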