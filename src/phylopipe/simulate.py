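"""Seeded synthetic datasets with ground truth for every pipeline stage.

The generator emulates the data pathologies of real mined transcriptome
and database sequence sets: allelic near-duplicates, within-taxon
paralogs, non-overlapping fragments, single-nucleotide frameshifts and
cross-domain contaminant copies — each planted at a configurable rate
and recorded in a truth table, so recovery can be asserted exactly.

It is *not* a realistic sequence-evolution simulator: substitutions are
uniform residue replacements with no rate heterogeneity and no indel
process beyond the planted events.  That is sufficient to exercise the
pipeline's thresholds; claims about real data rest on the thresholds
themselves, not on the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .guidetree import DistanceMatrix
from .seqio import read_newick, write_fasta

Record = tuple[str, str]

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "random_additive_tree",
    "simulate_paralog_family",
    "simulate_screen_tree",
]

_AA = "ARNDCQEGHILKMFPSTWYV"
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _v in _CODONS.values():
    _v.sort()

#: default taxon plan: four sampled eukaryotic major clades plus
#: bacterial and archaeal outgroups/donors — 30 taxa in all
DEFAULT_CLADE_PLAN = {"Am": 5, "Ex": 5, "Op": 5, "Pl": 5, "Ba": 6, "Za": 4}


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), n))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Exactly n_subs substitutions at distinct sites, always to a
    different residue."""
    if n_subs <= 0:
        return seq
    sites = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    out = list(seq)
    for i in sites:
        choices = [c for c in _AA if c != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def _mutate_rate(rng: np.random.Generator, seq: str, rate: float) -> str:
    return _mutate(rng, seq, int(round(rate * len(seq))))


def _reverse_translate(rng: np.random.Generator, prot: str) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in prot) + str(
        rng.choice(["TAA", "TAG", "TGA"])
    )


# ---------------------------------------------------------------------------
# random trees (used for NJ oracles and the contamination screen)


def random_additive_tree(
    n_leaves: int,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
    blen_range: tuple[float, float] = (0.05, 0.3),
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """A random binary topology with uniform branch lengths plus its
    (exactly additive) leaf-to-leaf distance matrix."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]
    labels = list(labels)
    if len(labels) != n_leaves:
        raise ValueError("labels/n_leaves mismatch")
    newick = _random_topology(list(labels), rng, blen_range)
    tree = read_newick(newick + ";", is_path=False)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
    return tree, DistanceMatrix(labels, d)


def _random_topology(labels: list[str], rng: np.random.Generator, blen_range) -> str:
    lo, hi = blen_range
    nodes = [f"{l}:{rng.uniform(lo, hi):.6f}" for l in labels]
    order = rng.permutation(len(nodes))
    nodes = [nodes[i] for i in order]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(lo, hi):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]})"


# ---------------------------------------------------------------------------
# sequence families with planted duplication clades


def simulate_paralog_family(
    rng: np.random.Generator,
    n_taxa: int = 10,
    dup_clades: dict[str, int] | None = None,
    length: int = 100,
    taxon_divergence: float = 0.15,
    paralog_divergence: float = 0.02,
) -> tuple[list[Record], dict[str, list[str]]]:
    """One protein per taxon plus planted within-taxon duplication clades.

    ``dup_clades`` maps a taxon index label (e.g. ``"ta03"``) to clade
    size; the extra copies diverge only ``paralog_divergence`` from
    their sibling, far below the between-taxon divergence, so they are
    monophyletic on any reasonable guide tree.  Returns the records and
    the truth map taxon-prefix -> planted duplicate names.
    """
    clades = ["Am", "Ex", "Op", "Pl", "Sr"]
    root = _rand_protein(rng, length)
    records: list[Record] = []
    truth: dict[str, list[str]] = {}
    for t in range(n_taxa):
        label = f"ta{t:02d}"
        prefix = f"{clades[t % len(clades)]}_s{chr(97 + t % 9)}_{label}"
        seq = _mutate_rate(rng, root, taxon_divergence)
        name = f"{prefix}_p0"
        records.append((name, seq))
        size = (dup_clades or {}).get(label, 1)
        dups = []
        for k in range(1, size):
            dup = _mutate_rate(rng, seq, paralog_divergence)
            # slightly shorter, so the original is the kept representative
            dup = dup[: length - 2 - k]
            dup_name = f"{prefix}_p{k}"
            records.append((dup_name, dup))
            dups.append(dup_name)
        if dups:
            truth[prefix] = dups
    return records, truth


# ---------------------------------------------------------------------------
# gene trees with planted cross-domain singletons


def simulate_screen_tree(
    rng: np.random.Generator,
    n_euk: int = 24,
    n_bact: int = 10,
    n_arch: int = 6,
    n_contaminants: int = 3,
    paired_intruder: bool = False,
) -> tuple[dendropy.Tree, list[str], list[str]]:
    """A domain-structured gene tree with contaminant singletons grafted
    deep inside a foreign domain.

    Returns (tree, planted contaminant leaf names, paired-intruder leaf
    names).  Paired intruders are two related foreign leaves placed
    sister to each other — real signal that must never be flagged.
    """
    euk_clades = ["Am", "Ex", "Op", "Pl"]
    euk = [
        f"{euk_clades[i % 4]}_e{chr(97 + i % 9)}_ta{i:02d}_{i}" for i in range(n_euk)
    ]
    bact = [f"Ba_b{chr(97 + i % 9)}_tb{i:02d}_{i}" for i in range(n_bact)]
    arch = [f"Za_a{chr(97 + i % 9)}_tc{i:02d}_{i}" for i in range(n_arch)]
    blocks = [
        _random_topology(block, rng, (0.05, 0.3))
        for block in (euk, bact, arch)
        if len(block) >= 2
    ]
    newick = "(" + ",".join(f"{b}:0.5" for b in blocks) + ");"
    tree = read_newick(newick, is_path=False)
    tree.is_rooted = False

    # one singleton per foreign block so the screen neighborhoods never
    # overlap: a euk label inside bacteria, one inside archaea, and a
    # bacterial label inside the eukaryotes
    plans = [
        (bact, lambda k: f"{euk_clades[k % 4]}_x{chr(97 + k)}_tx{k:02d}_c{k}"),
        (arch, lambda k: f"{euk_clades[(k + 1) % 4]}_x{chr(97 + k)}_tx{k:02d}_c{k}"),
        (euk, lambda k: f"Ba_x{chr(97 + k)}_tx{k:02d}_c{k}"),
    ]
    if n_contaminants > len(plans):
        raise ValueError("at most one planted singleton per domain block")
    contaminants: list[str] = []
    used_hosts: list[str] = []
    for k in range(n_contaminants):
        hosts, namer = plans[k]
        name = namer(k)
        host = _pick_host(tree, hosts, used_hosts, rng)
        _graft_at_leaf(tree, host, name, rng)
        used_hosts.append(host)
        contaminants.append(name)
    paired: list[str] = []
    if paired_intruder:
        host = _pick_host(tree, bact, used_hosts, rng)
        n1, n2 = "Op_ya_ty00_i1", "Op_ya_ty01_i2"
        _graft_at_leaf(tree, host, n1, rng)
        _graft_at_leaf(tree, n1, n2, rng)
        paired = [n1, n2]
    tree.update_taxon_namespace()
    return tree, contaminants, paired


def _leaf_distances(tree: dendropy.Tree, origin: str) -> dict[str, int]:
    """Edge-count distances from one leaf to every other leaf."""
    adjacency: dict[int, list[int]] = {}
    label: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        adjacency.setdefault(id(node), [])
        if node.is_leaf():
            label[id(node)] = node.taxon.label
        for child in node.child_nodes():
            adjacency[id(node)].append(id(child))
            adjacency.setdefault(id(child), []).append(id(node))
    start = next(i for i, l in label.items() if l == origin)
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for n in frontier:
            for nb in adjacency[n]:
                if nb not in dist:
                    dist[nb] = dist[n] + 1
                    nxt.append(nb)
        frontier = nxt
    return {label[i]: d for i, d in dist.items() if i in label}


def _pick_host(
    tree: dendropy.Tree,
    candidates: Sequence[str],
    used_hosts: Sequence[str],
    rng: np.random.Generator,
    min_separation: int = 5,
) -> str:
    """A grafting host deep inside its block and well away from hosts
    already used, so planted singletons stay singletons."""
    sep: dict[str, int] = {c: 10**6 for c in candidates}
    for h in used_hosts:
        d = _leaf_distances(tree, h)
        for c in candidates:
            sep[c] = min(sep[c], d.get(c, 10**6))
    # depth within the whole tree: distance from an arbitrary far leaf is a
    # poor proxy, so use mean distance to all leaves (central leaves score low)
    depth_proxy: dict[str, float] = {}
    for c in candidates:
        d = _leaf_distances(tree, c)
        depth_proxy[c] = float(np.mean(list(d.values())))
    ok = [c for c in candidates if sep[c] >= min_separation]
    pool = ok if ok else list(candidates)
    pool.sort(key=lambda c: (-depth_proxy[c], c))
    top = pool[: max(1, len(pool) // 3)]
    return str(top[int(rng.integers(0, len(top)))])


def _graft_at_leaf(tree: dendropy.Tree, host_label: str, new_label: str, rng) -> None:
    """Insert a new leaf as sister to an existing leaf."""
    host = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == host_label:
            host = leaf
            break
    if host is None:
        raise ValueError(f"host leaf {host_label!r} not found")
    parent = host.parent_node
    junction = dendropy.Node(edge_length=host.edge.length / 2)
    parent.remove_child(host)
    parent.add_child(junction)
    host.edge.length = host.edge.length / 2
    junction.add_child(host)
    taxon = dendropy.Taxon(label=new_label)
    tree.taxon_namespace.add_taxon(taxon)
    junction.add_child(dendropy.Node(taxon=taxon, edge_length=float(rng.uniform(0.05, 0.2))))


# ---------------------------------------------------------------------------
# the full dataset generator


@dataclass
class SimulationConfig:
    seed: int
    clade_plan: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLADE_PLAN))
    n_ogs: int = 40
    protein_length: tuple[int, int] = (80, 140)
    #: per-tree-level substitution fraction within a domain
    divergence: float = 0.04
    #: extra divergence separating domain root sequences
    domain_divergence: float = 0.15
    allele_rate: float = 0.15
    allele_identity: float = 0.99
    paralog_rate: float = 0.10
    fragment_rate: float = 0.10
    frameshift_rate: float = 0.10
    contamination_rate: float = 0.05
    n_refs_per_og: int = 4
    emit_nt: bool = True

    def __post_init__(self) -> None:
        rates = (
            self.allele_rate,
            self.paralog_rate,
            self.fragment_rate,
            self.frameshift_rate,
            self.contamination_rate,
        )
        if any(not (0 <= r <= 1) for r in rates) or sum(rates) > 1:
            raise ValueError("pathology rates must lie in [0,1] and sum to <= 1")
        if self.protein_length[0] < 60:
            raise ValueError("proteins shorter than 60 aa cannot host fragment windows")
        if not (0.98 <= self.allele_identity <= 1):
            raise ValueError("allele identity must be >= 0.98")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    taxa: dict[str, list[Record]]  # taxon prefix -> records
    og_refs: dict[str, list[Record]]  # og id -> reference proteins
    truth: pd.DataFrame  # name, taxon, og_id, pathology, role, detail

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "taxa").mkdir(parents=True, exist_ok=True)
        (outdir / "og_refs").mkdir(parents=True, exist_ok=True)
        for taxon in sorted(self.taxa):
            write_fasta(self.taxa[taxon], outdir / "taxa" / f"{taxon}.fasta")
        for og in sorted(self.og_refs):
            write_fasta(self.og_refs[og], outdir / "og_refs" / f"{og}.fasta")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


_DOMAIN_OF = {"Am": "eukaryote", "Ex": "eukaryote", "Op": "eukaryote", "Pl": "eukaryote",
              "Sr": "eukaryote", "EE": "eukaryote", "Ba": "bacteria", "Za": "archaea"}


def _evolve_down(rng, tree_labels: list[str], root_seq: str, rate: float) -> dict[str, str]:
    """Evolve a root protein down a random binary tree over the labels;
    each edge applies ``rate`` substitutions per site."""
    if len(tree_labels) == 1:
        return {tree_labels[0]: _mutate_rate(rng, root_seq, rate)}
    k = int(rng.integers(1, len(tree_labels)))
    left, right = tree_labels[:k], tree_labels[k:]
    out: dict[str, str] = {}
    out.update(_evolve_down(rng, left, _mutate_rate(rng, root_seq, rate), rate))
    out.update(_evolve_down(rng, right, _mutate_rate(rng, root_seq, rate), rate))
    return out


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate per-taxon sequence sets, OG reference proteins and the
    truth table.  Byte-identical output for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)

    # taxon roster
    taxa_by_domain: dict[str, list[str]] = {"eukaryote": [], "bacteria": [], "archaea": []}
    all_taxa: list[str] = []
    for clade in sorted(cfg.clade_plan):
        for i in range(cfg.clade_plan[clade]):
            prefix = f"{clade}_c{chr(97 + i % 9)}_t{clade.lower()}{i}"
            all_taxa.append(prefix)
            taxa_by_domain[_DOMAIN_OF[clade]].append(prefix)

    uid = 0

    def next_uid() -> str:
        nonlocal uid
        uid += 1
        return f"s{uid:06d}"

    taxa_records: dict[str, list[Record]] = {t: [] for t in all_taxa}
    og_refs: dict[str, list[Record]] = {}
    truth_rows: list[dict] = []

    pathologies = ["allele", "paralog", "fragment", "frameshift", "contaminant"]
    probs = np.array(
        [cfg.allele_rate, cfg.paralog_rate, cfg.fragment_rate, cfg.frameshift_rate, cfg.contamination_rate]
    )
    probs = np.append(probs, 1.0 - probs.sum())  # clean

    for g in range(cfg.n_ogs):
        og_id = f"OG{g:04d}"
        L = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        master = _rand_protein(rng, L)

        # domain roots and per-taxon clean proteins
        clean: dict[str, str] = {}
        for domain in ("eukaryote", "bacteria", "archaea"):
            members = taxa_by_domain[domain]
            if not members:
                continue
            droot = _mutate_rate(rng, master, cfg.domain_divergence)
            clean.update(_evolve_down(rng, members, droot, cfg.divergence))

        # OrthoMCL-style reference proteins: independent lineages off the master
        refs = []
        for r in range(cfg.n_refs_per_og):
            refs.append((f"{og_id}_ref{r}", _mutate_rate(rng, master, cfg.domain_divergence)))
        og_refs[og_id] = refs

        def emit(taxon: str, prot: str, pathology: str, role: str, detail: str = "") -> str:
            name = f"{taxon}_{next_uid()}"
            if cfg.emit_nt:
                nt = _reverse_translate(rng, prot)
                utr5 = "".join(rng.choice(list("ACGT"), int(rng.integers(0, 10))))
                utr3 = "".join(rng.choice(list("ACGT"), int(rng.integers(0, 10))))
                if pathology == "frameshift":
                    cpos = int(rng.integers(10, len(prot) - 10))
                    npos = 3 * cpos + int(rng.integers(0, 3))
                    nt = nt[:npos] + str(rng.choice(list("ACGT"))) + nt[npos:]
                    detail = f"codon={cpos}"
                seq = utr5 + nt + utr3
            else:
                seq = prot
            taxa_records[taxon].append((name, seq))
            truth_rows.append(
                dict(name=name, taxon=taxon, og_id=og_id, pathology=pathology, role=role, detail=detail)
            )
            return name

        for taxon in all_taxa:
            pathology = str(rng.choice(pathologies + ["clean"], p=probs))
            base = clean[taxon]
            if pathology == "fragment":
                w1 = base[: int(0.45 * len(base))]
                w2 = base[int(0.60 * len(base)) : int(0.95 * len(base))]
                emit(taxon, w1, "fragment", "keeper", "window=0")
                emit(taxon, w2, "fragment", "extra", "window=1")
                continue
            if pathology == "frameshift":
                emit(taxon, base, "frameshift", "keeper")
                continue
            emit(taxon, base, "clean", "keeper")
            if pathology == "allele":
                n_sub = max(1, int(round((1 - cfg.allele_identity) * len(base))))
                allele = _mutate(rng, base, n_sub)[: int(0.9 * len(base))]
                emit(taxon, allele, "allele", "extra")
            elif pathology == "paralog":
                paralog = _mutate_rate(rng, base, 0.05)[: len(base) - 3]
                emit(taxon, paralog, "paralog", "extra")
            elif pathology == "contaminant":
                domain = _DOMAIN_OF[taxon.split("_")[0]]
                foreign = [t for t in all_taxa if _DOMAIN_OF[t.split("_")[0]] != domain]
                source = foreign[int(rng.integers(0, len(foreign)))]
                cont = _mutate_rate(rng, clean[source], 0.02)[: int(0.85 * len(base))]
                emit(taxon, cont, "contaminant", "extra", f"source={source}")

    truth = pd.DataFrame(truth_rows, columns=["name", "taxon", "og_id", "pathology", "role", "detail"])
    return SimulatedDataset(cfg, taxa_records, og_refs, truth)
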