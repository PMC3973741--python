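"""Global pairwise alignment and the allele / non-homolog removal rules.

Candidate sequences for one taxon and one orthologous group are compared
all-against-all by global alignment (the EMBOSS-Needle contract: affine
gap penalties, free terminal gaps).  Two rules then thin the set:

* **too similar** — identity over the region of overlap strictly above
  ``id_cutoff`` (default 98%): the pair are alleles or very recent
  paralogs; the shorter is removed.
* **too dissimilar** — similarity (fraction of overlap columns with a
  positive substitution score) strictly below ``sim_cutoff`` (default
  75%): the pair are motif-sharing non-homologs or non-overlapping
  fragments; again the shorter is removed.

"Region of overlap" means alignment columns where neither row is gapped,
so terminal gaps never count against identity and non-overlapping
fragments are handled by the similarity rule, not the identity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "PairwiseResult",
    "RemovalRecord",
    "global_align",
    "refine_taxon_og",
    "write_removal_report",
]


def _nt_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array("ACGT", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 5.0 if a == b else -4.0
    return m


_MATRIX_CACHE: dict[str, substitution_matrices.Array] = {}


def load_matrix(name: str) -> substitution_matrices.Array:
    """A substitution matrix by name; ``NUC.5.-4`` is the builtin
    +5/−4 nucleotide matrix, anything else is read from Biopython's
    NCBI-format matrix collection (BLOSUM62, PAM250, ...)."""
    if name not in _MATRIX_CACHE:
        if name == "NUC.5.-4":
            _MATRIX_CACHE[name] = _nt_matrix()
        else:
            _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def read_matrix(path: str | Path) -> substitution_matrices.Array:
    """Read a substitution matrix in NCBI text format."""
    with open(path) as fh:
        return substitution_matrices.read(fh)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment.

    Defaults follow EMBOSS Needle: BLOSUM62 with gap open 10 / extend 0.5
    for proteins; +5/−4 with the same gap penalties for nucleotides.
    A gap of length k costs ``gap_open + (k−1)·gap_extend``; terminal
    gaps are free (Needle's default endweight=false).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if self.alphabet not in ("aa", "nt"):
            raise ValueError("alphabet must be 'aa' or 'nt'")
        if not (np.isfinite(self.gap_open) and np.isfinite(self.gap_extend)):
            raise ValueError("gap penalties must be finite")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes, must be >= 0")

    @classmethod
    def nucleotide(cls) -> "AlignmentParams":
        return cls(matrix_name="NUC.5.-4", alphabet="nt")

    @property
    def matrix(self) -> substitution_matrices.Array:
        return load_matrix(self.matrix_name)


DEFAULT_AA = AlignmentParams()
DEFAULT_NT = AlignmentParams.nucleotide()


@dataclass
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    overlap_len: int


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(params: AlignmentParams, mode: str = "global") -> Align.PairwiseAligner:
    key = (params, mode)
    if key not in _ALIGNER_CACHE:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = params.matrix
        al.open_gap_score = -params.gap_open
        al.extend_gap_score = -params.gap_extend
        if mode == "global":
            # Needle default: terminal gaps are free.
            al.open_end_gap_score = 0.0
            al.extend_end_gap_score = 0.0
        _ALIGNER_CACHE[key] = al
    return _ALIGNER_CACHE[key]


def _validate(seq: str, params: AlignmentParams, label: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence {label!r}")
    alphabet = set(str(a) for a in params.matrix.alphabet)
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"sequence {label!r} has residues outside the matrix alphabet: {sorted(bad)}")


def global_align(a: str, b: str, params: AlignmentParams = DEFAULT_AA) -> PairwiseResult:
    """Optimal global alignment of two sequences with affine gaps.

    Identity and similarity are percentages over the overlap (columns
    where neither row is gapped); a zero-length overlap yields 0 for
    both.
    """
    a, b = a.upper(), b.upper()
    _validate(a, params, "a")
    _validate(b, params, "b")
    aln = _aligner(params).align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matrix = params.matrix
    matches = 0
    similar = 0
    overlap = 0
    for ra, rb in zip(sa, sb):
        if ra == "-" or rb == "-":
            continue
        overlap += 1
        if ra == rb:
            matches += 1
        if matrix[ra, rb] > 0:
            similar += 1
    ident = 100.0 * matches / overlap if overlap else 0.0
    simil = 100.0 * similar / overlap if overlap else 0.0
    return PairwiseResult(sa, sb, float(aln.score), ident, simil, overlap)


@dataclass
class RemovalRecord:
    name: str
    reason: str  # too_similar | too_dissimilar
    partner: str
    identity_pct: float
    similarity_pct: float


def refine_taxon_og(
    records: Sequence[tuple[str, str]],
    id_cutoff: float = 98.0,
    sim_cutoff: float = 75.0,
    params: AlignmentParams = DEFAULT_AA,
) -> tuple[list[tuple[str, str]], list[RemovalRecord]]:
    """Remove alleles / recent paralogs and non-homologous fragments
    among same-taxon candidates for one orthologous group.

    Records are visited longest first (length ties broken by name); each
    candidate is compared against all longer survivors and removed as
    soon as one pair is strictly above ``id_cutoff`` identity
    (``too_similar``) or strictly below ``sim_cutoff`` similarity
    (``too_dissimilar``).  The longest input sequence can never be
    removed, and re-running on the output removes nothing.
    """
    if not (0 < id_cutoff <= 100) or not (0 <= sim_cutoff <= 100):
        raise ValueError("cutoffs must lie in (0, 100]")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    kept: list[tuple[str, str]] = []
    removed: list[RemovalRecord] = []
    for name, seq in ordered:
        verdict: RemovalRecord | None = None
        for kname, kseq in kept:
            res = global_align(seq, kseq, params)
            if res.identity_pct > id_cutoff:
                verdict = RemovalRecord(name, "too_similar", kname, res.identity_pct, res.similarity_pct)
                break
            if res.similarity_pct < sim_cutoff:
                verdict = RemovalRecord(name, "too_dissimilar", kname, res.identity_pct, res.similarity_pct)
                break
        if verdict is None:
            kept.append((name, seq))
        else:
            removed.append(verdict)
    # restore input order among survivors
    order = {name: i for i, (name, _) in enumerate(records)}
    kept.sort(key=lambda r: order[r[0]])
    return kept, removed


def write_removal_report(removed: Iterable[RemovalRecord], path: str | Path) -> None:
    lines = ["name\treason\tpartner\tidentity\tsimilarity"]
    for r in removed:
        lines.append(f"{r.name}\t{r.reason}\t{r.partner}\t{r.identity_pct:.2f}\t{r.similarity_pct:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
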