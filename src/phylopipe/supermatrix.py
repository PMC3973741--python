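"""Supermatrix concatenation, occupancy filtering and missing-data masking.

One-sequence-per-taxon gene alignments are concatenated into a single
matrix, one row per taxon (10-character code prefix — sequence uids are
dropped, a row now spans many genes), with a partition table recording
each gene's column range, alphabet and substitution-model label
(GTRGAMMA for nucleotide partitions such as an appended SSU alignment,
PROTGAMMALG for proteins).  Cells absent for a taxon are filled with the
missing symbol.

Two occupancy filters follow, in this order: taxa present in fewer than
``min_genes`` partitions are dropped, then columns with strictly more
than ``max_missing`` missing data are deleted (a column missing in
exactly half the rows survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .confalign import AlignmentMatrix
from .naming import parse_name

__all__ = [
    "Partition",
    "Supermatrix",
    "concatenate",
    "filter_taxa_min_genes",
    "mask_missing_columns",
    "write_supermatrix",
    "read_phylip",
]

MISSING = "-"
_MISSING_ON_READ = {"-", "?", "X"}

DEFAULT_MODELS = {"aa": "PROTGAMMALG", "nt": "GTRGAMMA"}


@dataclass(frozen=True)
class Partition:
    name: str
    kind: str  # "aa" | "nt"
    start: int  # 1-based inclusive
    end: int
    model_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("aa", "nt"):
            raise ValueError(f"partition {self.name}: kind must be aa or nt")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"partition {self.name}: bad range {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[Partition]

    def __post_init__(self) -> None:
        width = sum(p.length for p in self.partitions)
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != width:
                raise ValueError(f"row {taxon} has {len(row)} columns, partitions sum to {width}")
        starts = sorted((p.start, p.end) for p in self.partitions)
        pos = 1
        for s, e in starts:
            if s != pos:
                raise ValueError("partitions do not tile the matrix")
            pos = e + 1

    @property
    def n_cols(self) -> int:
        return sum(p.length for p in self.partitions)

    def occupancy(self) -> dict[str, int]:
        """Per-taxon count of partitions holding at least one residue."""
        out: dict[str, int] = {}
        for taxon, row in zip(self.taxa, self.rows):
            count = 0
            for p in self.partitions:
                cell = row[p.start - 1 : p.end]
                if any(c not in _MISSING_ON_READ for c in cell):
                    count += 1
            out[taxon] = count
        return out


def _taxon_of(name: str) -> str:
    parts = name.split("_")
    if len(parts) == 3:  # already a bare taxon prefix
        from .naming import TaxonCode

        return TaxonCode(*parts).prefix
    return parse_name(name).code.prefix


def concatenate(
    og_alignments: Mapping[str, AlignmentMatrix],
    extra_partitions: Sequence[tuple[str, str, AlignmentMatrix]] = (),
    models: Mapping[str, str] = DEFAULT_MODELS,
) -> Supermatrix:
    """Concatenate one-per-taxon OG alignments plus optional extra
    partitions (e.g. an SSU alignment), OGs in sorted id order.

    Row names in the inputs may be full sequence names or bare taxon
    prefixes; rows are keyed by taxon prefix and a taxon may appear at
    most once per gene.  Missing taxon×gene cells are filled with the
    missing symbol.
    """
    blocks: list[tuple[str, str, AlignmentMatrix]] = [
        (og_id, "aa", og_alignments[og_id]) for og_id in sorted(og_alignments)
    ]
    blocks += [(name, kind, aln) for name, kind, aln in extra_partitions]

    keyed_blocks: list[tuple[str, str, dict[str, str], int]] = []
    all_taxa: set[str] = set()
    for name, kind, aln in blocks:
        if not aln.rows:
            raise ValueError(f"partition {name}: empty alignment")
        keyed: dict[str, str] = {}
        for row_name, row in zip(aln.names, aln.rows):
            taxon = _taxon_of(row_name)
            if taxon in keyed:
                raise ValueError(f"partition {name}: two sequences for taxon {taxon}")
            keyed[taxon] = row
        keyed_blocks.append((name, kind, keyed, aln.n_cols))
        all_taxa |= set(keyed)

    taxa = sorted(all_taxa)
    partitions: list[Partition] = []
    pos = 1
    parts_rows: dict[str, list[str]] = {t: [] for t in taxa}
    for name, kind, keyed, width in keyed_blocks:
        partitions.append(Partition(name, kind, pos, pos + width - 1, models[kind]))
        pos += width
        for t in taxa:
            parts_rows[t].append(keyed.get(t, MISSING * width))
    rows = ["".join(parts_rows[t]) for t in taxa]
    return Supermatrix(taxa, rows, partitions)


def filter_taxa_min_genes(sm: Supermatrix, min_genes: int = 20) -> Supermatrix:
    """Drop taxa occupying fewer than ``min_genes`` partitions."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    occ = sm.occupancy()
    keep = [i for i, t in enumerate(sm.taxa) if occ[t] >= min_genes]
    return Supermatrix([sm.taxa[i] for i in keep], [sm.rows[i] for i in keep], list(sm.partitions))


def mask_missing_columns(
    sm: Supermatrix, max_missing: float = 0.5
) -> tuple[Supermatrix, list[int]]:
    """Delete columns with strictly more than ``max_missing`` missing
    cells; partition ranges are recomputed and empty partitions dropped.
    Returns the masked matrix and the deleted 0-based column indices."""
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must lie in [0, 1]")
    if not sm.rows:
        return sm, []
    arr = np.array([list(r) for r in sm.rows])
    missing = np.isin(arr, list(_MISSING_ON_READ))
    frac = missing.mean(axis=0)
    masked = [int(c) for c in np.nonzero(frac > max_missing)[0]]
    keep = frac <= max_missing
    rows = ["".join(row[keep]) for row in arr]

    partitions: list[Partition] = []
    pos = 1
    for p in sorted(sm.partitions, key=lambda p: p.start):
        surviving = int(keep[p.start - 1 : p.end].sum())
        if surviving == 0:
            continue
        partitions.append(replace(p, start=pos, end=pos + surviving - 1))
        pos += surviving
    return Supermatrix(list(sm.taxa), rows, partitions), masked


# ---------------------------------------------------------------------------
# writers


def write_supermatrix(sm: Supermatrix, outdir: str | Path, stem: str = "supermatrix") -> dict[str, Path]:
    """Write relaxed PHYLIP, FASTA, a RAxML-style partition file and an
    occupancy table.  Output is bit-exact across runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(set(sm.taxa)) != len(sm.taxa):
        raise ValueError("duplicate taxon-level row names")
    paths = {
        "phylip": outdir / f"{stem}.phy",
        "fasta": outdir / f"{stem}.fasta",
        "partitions": outdir / f"{stem}.partitions.txt",
        "occupancy": outdir / f"{stem}.occupancy.tsv",
    }
    pad = max((len(t) for t in sm.taxa), default=10) + 2
    with open(paths["phylip"], "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_cols}\n")
        for t, row in zip(sm.taxa, sm.rows):
            fh.write(f"{t:<{pad}}{row}\n")
    with open(paths["fasta"], "w") as fh:
        for t, row in zip(sm.taxa, sm.rows):
            fh.write(f">{t}\n{row}\n")
    with open(paths["partitions"], "w") as fh:
        for p in sorted(sm.partitions, key=lambda p: p.start):
            fh.write(f"# {p.name}: {p.model_label}\n")
        for p in sorted(sm.partitions, key=lambda p: p.start):
            kind = "DNA" if p.kind == "nt" else "LG"
            fh.write(f"{kind}, {p.name} = {p.start}-{p.end}\n")
    occ = sm.occupancy()
    with open(paths["occupancy"], "w") as fh:
        fh.write("taxon\tpartitions_present\n")
        for t in sm.taxa:
            fh.write(f"{t}\t{occ[t]}\n")
    return paths


def read_phylip(path: str | Path) -> tuple[list[str], list[str]]:
    """Round-trip reader for the relaxed PHYLIP written above."""
    lines = Path(path).read_text().splitlines()
    n, width = (int(x) for x in lines[0].split())
    taxa: list[str] = []
    rows: list[str] = []
    for line in lines[1 : n + 1]:
        name, row = line.split(None, 1)
        taxa.append(name)
        rows.append(row.strip())
        if len(rows[-1]) != width:
            raise ValueError(f"row {name}: expected {width} columns")
    return taxa, rows
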