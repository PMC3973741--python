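"""Ortholog-group assignment, contamination prescreen and protein inference.

Candidate sequences from a taxon are compared against the reference
proteins of each orthologous group (OG).  The builtin search is
desk-scale BLAST-like machinery: exact amino-acid k-mer seeds (k=4)
select candidate references, which are then scored by Smith–Waterman
local alignment in raw substitution-matrix units.  An external-table
backend accepts precomputed tabular hits (the common 12-column blast
dialect) instead.

Nucleotide records are translated against their best reference with
frameshift recovery: if significant hits occur in more than one reading
frame, the translation switches frame at the inferred breakpoint,
skipping nucleotides one at a time until the downstream frame realigns.
At most about one residue is lost per breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .pairwise import AlignmentParams, DEFAULT_AA, _aligner
from .naming import taxon_prefix

Record = tuple[str, str]

__all__ = [
    "OrthologGroup",
    "SearchHit",
    "NoFrameError",
    "ProteinInferenceError",
    "assign_to_ogs",
    "prescreen_contaminants",
    "infer_protein",
    "read_external_hits",
    "bucket_filename",
]

_NT_CHARS = set("ACGTUN")


def looks_nucleotide(seq: str) -> bool:
    """Heuristic alphabet sniff: ACGT(U/N) content above 95%."""
    if not seq:
        return False
    hits = sum(1 for c in seq.upper() if c in _NT_CHARS)
    return hits / len(seq) >= 0.95


@dataclass
class OrthologGroup:
    """An OG identifier plus its reference proteins and per-taxon members."""

    og_id: str
    reference_proteins: list[Record]
    members: dict[str, list[Record]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference_proteins:
            raise ValueError(f"OG {self.og_id}: empty reference set")


@dataclass
class SearchHit:
    query: str
    target: str
    og_id: str
    score: float
    frame: int  # +1..+3 / -1..-3 for nt queries, 0 for aa
    query_start: int  # 1-based inclusive, on the query as given
    query_end: int


class NoFrameError(ValueError):
    """No reading frame of the query has a qualifying hit to the reference."""


class ProteinInferenceError(ValueError):
    """Translation produced an internal stop on the chosen path."""


# ---------------------------------------------------------------------------
# builtin k-mer seeded local search


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Exact k-mer seed index over a set of reference proteins."""

    def __init__(self, refs: Sequence[tuple[str, str, str]], k: int = 4):
        # refs: (og_id, name, sequence)
        self.k = k
        self.refs = list(refs)
        self._index: dict[str, set[int]] = {}
        for i, (_og, _name, seq) in enumerate(self.refs):
            for kmer in _kmers(seq, k):
                self._index.setdefault(kmer, set()).add(i)

    def candidates(self, query_aa: str) -> set[int]:
        out: set[int] = set()
        for kmer in _kmers(query_aa, self.k):
            out |= self._index.get(kmer, set())
        return out


def _local_align(query_aa: str, ref_aa: str, params: AlignmentParams):
    """Local alignment score plus aligned spans (query aa, ref aa)."""
    aln = _aligner(params, mode="local").align(query_aa, ref_aa)[0]
    tblocks, qblocks = aln.aligned
    q0, q1 = int(tblocks[0][0]), int(tblocks[-1][1])
    r0, r1 = int(qblocks[0][0]), int(qblocks[-1][1])
    return float(aln.score), q0, q1, r0, r1


def _translate(nt: str, offset: int, table: int) -> str:
    usable = (len(nt) - offset) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(nt[offset : offset + usable]).translate(table=table))


def _frames(nt: str, table: int):
    """All six reading frames: (frame label, strand seq, offset, protein)."""
    rc = str(Seq(nt).reverse_complement())
    for offset in range(3):
        yield offset + 1, nt, offset, _translate(nt, offset, table)
    for offset in range(3):
        yield -(offset + 1), rc, offset, _translate(rc, offset, table)


def best_local_score(
    query: str,
    refs: Sequence[Record],
    params: AlignmentParams = DEFAULT_AA,
    k: int = 4,
    genetic_code: int = 1,
) -> tuple[float, str, int]:
    """Best local-alignment score of a (possibly nucleotide) query against
    a reference protein set.  Returns (score, ref name, frame)."""
    index = KmerIndex([("", name, seq) for name, seq in refs], k=k)
    best = (0.0, "", 0)
    if looks_nucleotide(query):
        frames = [(f, prot) for f, _s, _o, prot in _frames(query, genetic_code) if prot]
    else:
        frames = [(0, query.upper())]
    for frame, prot in frames:
        prot = _sanitize_aa(prot)
        for i in index.candidates(prot):
            _og, name, refseq = index.refs[i]
            score, *_ = _local_align(prot, refseq, params)
            # ties broken toward forward strand / earlier frame / ref name
            if score > best[0]:
                best = (score, name, frame)
    return best


_AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize_aa(prot: str) -> str:
    return "".join(c if c in _AA_ALPHABET else "X" for c in prot.upper())


def assign_to_ogs(
    taxon_records: Sequence[Record],
    og_set: Sequence[OrthologGroup],
    min_score: float = 50.0,
    backend: str = "builtin",
    external_hits: Sequence[SearchHit] | None = None,
    params: AlignmentParams = DEFAULT_AA,
    k: int = 4,
    genetic_code: int = 1,
) -> tuple[dict[str, list[Record]], dict[str, SearchHit], list[tuple[str, str]]]:
    """Assign each query to the single OG of its best-scoring hit.

    Returns (og_id -> records, query name -> best hit, dropped
    (name, reason) pairs).  Queries with no hit at ``min_score`` or above
    are dropped; each record lands in at most one OG bucket.
    """
    if not og_set:
        raise ValueError("empty OG set")
    if backend not in ("builtin", "external-table"):
        raise ValueError(f"unknown backend {backend!r}")

    buckets: dict[str, list[Record]] = {}
    hits: dict[str, SearchHit] = {}
    dropped: list[tuple[str, str]] = []

    if backend == "external-table":
        known = {og.og_id for og in og_set}
        target_og = {name: og.og_id for og in og_set for name, _ in og.reference_proteins}
        best: dict[str, SearchHit] = {}
        for hit in external_hits or []:
            og_id = hit.og_id or target_og.get(hit.target, "")
            if og_id not in known:
                raise ValueError(f"external hit references unknown OG {hit.og_id!r} / target {hit.target!r}")
            if hit.query not in best or hit.score > best[hit.query].score:
                best[hit.query] = SearchHit(
                    hit.query, hit.target, og_id, hit.score, hit.frame, hit.query_start, hit.query_end
                )
        for name, seq in taxon_records:
            hit = best.get(name)
            if hit is None or hit.score < min_score:
                dropped.append((name, "no_hit"))
                continue
            hits[name] = hit
            buckets.setdefault(hit.og_id, []).append((name, seq))
        return buckets, hits, dropped

    ref_triples = [(og.og_id, name, seq) for og in og_set for name, seq in og.reference_proteins]
    index = KmerIndex(ref_triples, k=k)
    fallback_index: KmerIndex | None = None

    def search(record: Record, idx: KmerIndex) -> SearchHit | None:
        name, seq = record
        nt = looks_nucleotide(seq)
        if nt:
            frames = [
                (f, offset, prot)
                for f, _strand, offset, prot in _frames(seq, genetic_code)
                if prot
            ]
        else:
            frames = [(0, 0, _sanitize_aa(seq))]
        best_hit: SearchHit | None = None
        for frame, offset, prot in frames:
            prot = _sanitize_aa(prot)
            for i in idx.candidates(prot):
                og_id, ref_name, ref_seq = idx.refs[i]
                score, q0, q1, _r0, _r1 = _local_align(prot, ref_seq, params)
                if best_hit is not None and score <= best_hit.score:
                    continue
                if nt:
                    s0, s1 = offset + 3 * q0, offset + 3 * q1  # strand coords
                    if frame > 0:
                        qs, qe = s0 + 1, s1
                    else:
                        qs, qe = len(seq) - s1 + 1, len(seq) - s0
                else:
                    qs, qe = q0 + 1, q1
                best_hit = SearchHit(name, ref_name, og_id, score, frame, qs, qe)
        return best_hit

    for name, seq in taxon_records:
        best_hit = search((name, seq), index)
        if (best_hit is None or best_hit.score < min_score) and k > 3:
            # short or highly diverged queries can miss every exact k-mer
            # seed; retry with a more sensitive seed length
            if fallback_index is None:
                fallback_index = KmerIndex(ref_triples, k=3)
            best_hit = search((name, seq), fallback_index)
        if best_hit is None or best_hit.score < min_score:
            dropped.append((name, "no_hit"))
        else:
            hits[name] = best_hit
            buckets.setdefault(best_hit.og_id, []).append((name, seq))
    return buckets, hits, dropped


def bucket_filename(taxon: str, og_id: str) -> str:
    """One file per taxon/OG combination."""
    return f"{taxon}_{og_id}.fasta"


# ---------------------------------------------------------------------------
# contamination prescreen


def prescreen_contaminants(
    records: Sequence[Record],
    target_refs: Sequence[Record],
    contaminant_refs: Sequence[Record],
    margin: float = 0.0,
    min_score: float = 50.0,
    params: AlignmentParams = DEFAULT_AA,
    genetic_code: int = 1,
) -> tuple[list[Record], list[Record], list[Record]]:
    """Keep records whose best score against the taxon-of-interest
    references beats their best score against known contaminant
    references by at least ``margin``.

    Records scoring below ``min_score`` against both sets go to
    ``no_hit`` — likely real data lost, but without robust evidence of
    homology it cannot be trusted.
    """
    if not target_refs or not contaminant_refs:
        raise ValueError("both reference sets must be nonempty")
    kept: list[Record] = []
    flagged: list[Record] = []
    no_hit: list[Record] = []
    for name, seq in records:
        s_t, *_ = best_local_score(seq, target_refs, params, genetic_code=genetic_code)
        s_c, *_ = best_local_score(seq, contaminant_refs, params, genetic_code=genetic_code)
        if s_t < min_score and s_c < min_score:
            no_hit.append((name, seq))
        elif s_t - s_c >= margin:
            kept.append((name, seq))
        else:
            flagged.append((name, seq))
    return kept, flagged, no_hit


# ---------------------------------------------------------------------------
# frameshift-aware protein inference


@dataclass
class FrameshiftReport:
    strand: int  # +1 or -1
    frames: list[int]  # frame labels used, in order along the protein
    breakpoints: list[int]  # residue index in the output protein at each switch
    skipped_nt: int = 0

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)


def infer_protein(
    nt_record: Record,
    best_reference: str,
    genetic_code: int = 1,
    min_score: float = 50.0,
    params: AlignmentParams = DEFAULT_AA,
) -> tuple[Record, FrameshiftReport]:
    """Infer the protein of a nucleotide record using its best OG reference.

    Each of the six reading frames is aligned locally against the
    reference.  A single qualifying frame is translated directly over
    its reference-supported region.  Qualifying hits in multiple frames
    on one strand indicate a frameshift: the translation switches frames
    at the midpoint between the last reference-aligned codon of the
    upstream frame and the first of the downstream frame, skipping the
    few nucleotides needed to realign.
    """
    name, nt = nt_record
    nt = nt.upper().replace("U", "T")
    if len(nt) < 3:
        raise NoFrameError(f"{name}: shorter than one codon")
    ref = best_reference.upper()

    segs = []  # (frame, strand, offset, score, q0, q1, r0, r1, strand_seq)
    for frame, strand_seq, offset, prot in _frames(nt, genetic_code):
        if not prot:
            continue
        prot = _sanitize_aa(prot)
        score, q0, q1, r0, r1 = _local_align(prot, ref, params)
        segs.append((frame, offset, score, q0, q1, r0, r1, strand_seq))

    qualifying = [s for s in segs if s[2] >= min_score]
    if not qualifying:
        raise NoFrameError(f"{name}: no reading frame has a qualifying hit (reason: no_frame)")

    # choose the strand holding the best hit; forward wins ties
    best = max(qualifying, key=lambda s: (s[2], s[0] > 0))
    strand = 1 if best[0] > 0 else -1
    strand_segs = [s for s in qualifying if (s[0] > 0) == (strand > 0)]
    strand_seq = strand_segs[0][7]

    # drop frames whose reference span is contained in another's
    strand_segs.sort(key=lambda s: (s[5], -s[6]))
    chain = []
    for s in strand_segs:
        if chain and s[6] <= chain[-1][6]:
            continue
        chain.append(s)
    # segments must also advance along the query; otherwise fall back
    nt_starts = [s[1] + 3 * s[3] for s in chain]
    if any(b <= a for a, b in zip(nt_starts, nt_starts[1:])):
        chain = [best]

    # For every chained frame, map reference positions to query codons by
    # global alignment (free end gaps), so the translation covers the whole
    # reference-supported span even where terminal divergence makes the
    # local alignment stop early.  With more than one frame, each switch is
    # placed at the reference position maximizing exact matches of the
    # upstream frame before it plus the downstream frame after it.
    maps = []  # per segment: dict ref_pos -> (codon_start_nt, matches_ref)
    for seg in chain:
        frame, offset, _score, seg_q0, seg_q1, _r0, _r1, _sseq = seg
        prot = _sanitize_aa(_translate(strand_seq, offset, genetic_code))
        aln = _aligner(params).align(prot, ref)[0]
        tblocks, qblocks = aln.aligned
        # the open reading frame around the locally aligned window: chance
        # pairings beyond a stop codon are UTR junk, not coding sequence
        stops = [p for p, c in enumerate(prot) if c == "*"]
        orf_lo = max([s + 1 for s in stops if s < seg_q0], default=0)
        orf_hi = min([s for s in stops if s >= max(seg_q1 - 1, seg_q0)], default=len(prot))
        m: dict[int, tuple[int, bool]] = {}
        for (t0, t1), (r0, r1) in zip(tblocks, qblocks):
            for k in range(t1 - t0):
                qa, r = t0 + k, r0 + k
                # trust only the locally aligned window within the ORF
                if qa < max(seg_q0 - 5, orf_lo) or qa >= min(seg_q1 + 5, orf_hi):
                    continue
                m[r] = (offset + 3 * qa, prot[qa] == ref[r])
        maps.append(m)

    L = len(ref)
    boundaries: list[int] = []
    prev_b = 0
    for i in range(len(chain) - 1):
        up, down = maps[i], maps[i + 1]
        up_match = np.cumsum([1 if (r in up and up[r][1]) else 0 for r in range(L)])
        down_match = np.cumsum([1 if (r in down and down[r][1]) else 0 for r in range(L)][::-1])[::-1]
        best_b, best_val = prev_b, -1
        for b in range(prev_b, L + 1):
            val = (up_match[b - 1] if b > 0 else 0) + (down_match[b] if b < L else 0)
            if val > best_val:
                best_val, best_b = val, b
        boundaries.append(best_b)
        prev_b = best_b

    out_res: list[str] = []
    breakpoints: list[int] = []
    frames_used = [seg[0] for seg in chain]
    skipped = 0
    bounds = [0] + boundaries + [L]
    last_nt_end: int | None = None
    for i, seg in enumerate(chain):
        lo, hi = bounds[i], bounds[i + 1]
        seg_map = dict(maps[i])
        mapped = sorted(r for r in seg_map if lo <= r < hi)
        # free end gaps clip terminal mismatch runs, so extend the mapped
        # span diagonally (bounded) to keep the translation full length
        if mapped and i == 0:
            r0, c0 = mapped[0], seg_map[mapped[0]][0]
            for k in range(1, 7):
                r, c = r0 - k, c0 - 3 * k
                if r < lo or c < 0 or r in seg_map:
                    break
                if _translate_span(strand_seq, c, c + 3, genetic_code) == "*":
                    break  # the coding region genuinely ends here
                seg_map[r] = (c, False)
        if mapped and i == len(chain) - 1:
            r1, c1 = mapped[-1], seg_map[mapped[-1]][0]
            for k in range(1, 7):
                r, c = r1 + k, c1 + 3 * k
                if r >= hi or c + 3 > len(strand_seq) or r in seg_map:
                    break
                if _translate_span(strand_seq, c, c + 3, genetic_code) == "*":
                    break
                seg_map[r] = (c, False)
        first_of_seg = True
        for r in range(lo, hi):
            if r not in seg_map:
                continue
            cstart = seg_map[r][0]
            codon = _translate_span(strand_seq, cstart, cstart + 3, genetic_code)
            if codon == "*":  # chance-aligned junk at a boundary; drop it
                continue
            if last_nt_end is not None and cstart < last_nt_end:
                continue
            if i > 0 and first_of_seg and last_nt_end is not None:
                skipped += max(0, cstart - last_nt_end)
            first_of_seg = False
            out_res.append(codon)
            last_nt_end = cstart + 3
        if i < len(chain) - 1:
            breakpoints.append(len(out_res))

    protein = "".join(out_res).rstrip("*")
    if "*" in protein:
        raise ProteinInferenceError(f"{name}: internal stop in inferred protein (reason: internal_stop)")
    report = FrameshiftReport(strand, frames_used, breakpoints, skipped)
    return (name, protein), report


def _translate_span(strand_seq: str, start: int, end: int, table: int) -> str:
    usable = (end - start) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(strand_seq[start : start + usable]).translate(table=table))


# ---------------------------------------------------------------------------
# external tabular hits (12-column blast-like dialect)


def read_external_hits(
    path: str | Path, target_og: Mapping[str, str] | None = None
) -> list[SearchHit]:
    """Read hits in the widely used 12-column tabular dialect:
    query, target, %id, length, mismatches, gapopens, qstart, qend,
    tstart, tend, evalue, bitscore."""
    hits: list[SearchHit] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ValueError(f"expected 12 tab-separated columns, got {len(f)}: {line!r}")
        query, target = f[0], f[1]
        qstart, qend = int(f[6]), int(f[7])
        score = float(f[11])
        og = target_og.get(target, "") if target_og else ""
        frame = 0
        if qstart > qend:  # minus-strand convention in tabular reports
            qstart, qend, frame = qend, qstart, -1
        hits.append(SearchHit(query, target, og, score, frame, qstart, qend))
    return hits
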