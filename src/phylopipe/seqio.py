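"""Thin FASTA / Newick I/O helpers.

FASTA goes through Biopython; trees through dendropy.  Records are plain
``(name, sequence)`` tuples throughout the package — light enough to keep
every stage trivially serialisable, and convertible to ``SeqRecord`` at
the boundary.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Record = tuple[str, str]


def read_fasta(path: str | Path) -> list[Record]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[Record], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def fasta_string(records: Iterable[Record]) -> str:
    buf = StringIO()
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records], buf, "fasta"
    )
    return buf.getvalue()


def read_newick(source: str | Path, *, is_path: bool = True) -> dendropy.Tree:
    """Read a Newick tree, preserving underscores in unquoted labels."""
    if is_path:
        return dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    if path is not None:
        Path(path).write_text(s)
    return s
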