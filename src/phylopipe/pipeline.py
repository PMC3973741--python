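"""Pipeline orchestration: taxon stage, gene stage, concatenation.

The taxon stage mines and refines data per taxon: assign candidate
sequences to orthologous groups, optionally prescreen known-contaminant
hosts, infer proteins from nucleotide data (with frameshift recovery)
and apply the pairwise allele / non-homolog removal rules.  Each taxon
is independent.

The gene stage combines the per-taxon buckets per OG: collapse in-group
paralogs on guide trees (skippable when all paralogs should be kept),
run the two-pass confidence alignment filter, build a gene tree, screen
it for cross-domain singletons, and finally select one sequence per
taxon.  Each OG is independent — the work is trivially parallelizable
by invoking OGs on separate machines.  Two outputs per OG: the
paralog-retaining screened alignment (for reconciliation-style
analyses) and the one-per-taxon alignment (for concatenation).

Every removal at any stage lands in exactly one audit log entry with a
reason code; inputs are processed in sorted order so reruns and
shuffled inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .confalign import (
    AllSequencesRemoved,
    AlignmentMatrix,
    GuidanceConfig,
    guidance_filter,
)
from .guidetree import alignment_pdistance, collapse_ingroup_paralogs, nj_tree
from .homology import NoFrameError, OrthologGroup, ProteinInferenceError, assign_to_ogs, infer_protein, prescreen_contaminants
from .naming import DEFAULT_DOMAIN_TABLE, DomainTable
from .orthoselect import select_orthologs
from .pairwise import AlignmentParams, DEFAULT_AA, refine_taxon_og
from .seqio import read_newick
from .supermatrix import Supermatrix, concatenate, filter_taxa_min_genes, mask_missing_columns, write_supermatrix
from .treescreen import find_misplaced_leaves, remove_flagged

Record = tuple[str, str]

logger = logging.getLogger("phylopipe")

__all__ = ["PipelineConfig", "run_taxon_stage", "run_gene_stage", "run_concatenation"]


@dataclass
class PipelineConfig:
    """All tunable thresholds, defaulting to the published values."""

    id_cutoff: float = 98.0  # % identity above which the shorter of a pair is an allele
    sim_cutoff: float = 75.0  # % similarity below which the shorter is a non-homolog
    min_score: float = 50.0  # raw local-alignment score for a qualifying hit
    prescreen_margin: float = 0.0
    sp_seq_cutoff: float = 0.5
    sp_col_cutoff: float = 0.4
    n_alternatives: int = 10
    min_neighbors: int = 3
    max_iter: int = 5  # paralog-collapse iterations
    min_genes: int = 20
    max_missing: float = 0.5
    skip_collapse: bool = False
    drop_ogs_without_taxa: Sequence[str] = ()  # drop OGs lacking all of these taxa
    seed: int = 0
    genetic_code: int = 1
    params: AlignmentParams = field(default_factory=lambda: DEFAULT_AA)
    domains: DomainTable = field(default_factory=lambda: DEFAULT_DOMAIN_TABLE)

    def guidance(self, seed_offset: int = 0) -> GuidanceConfig:
        return GuidanceConfig(
            self.sp_seq_cutoff,
            self.sp_col_cutoff,
            self.n_alternatives,
            self.seed + seed_offset,
            self.params,
        )


def _audit(rows: list[dict], stage: str, name: str, reason: str, **extra) -> None:
    rows.append(dict(stage=stage, name=name, reason=reason, **extra))


@dataclass
class TaxonStageResult:
    buckets: dict[tuple[str, str], list[Record]]  # (taxon, og_id) -> aa records
    audit: pd.DataFrame

    def og_records(self) -> dict[str, list[Record]]:
        out: dict[str, list[Record]] = {}
        for (taxon, og_id), records in sorted(self.buckets.items()):
            out.setdefault(og_id, []).extend(records)
        return out


def run_taxon_stage(
    taxa: Mapping[str, Sequence[Record]],
    og_set: Sequence[OrthologGroup],
    config: PipelineConfig = PipelineConfig(),
    prescreen_refs: Mapping[str, tuple[Sequence[Record], Sequence[Record]]] | None = None,
    external_hits: Mapping[str, Sequence] | None = None,
) -> TaxonStageResult:
    """Mine and refine each taxon independently.

    ``taxa`` maps taxon prefix to its records (nt or aa).
    ``prescreen_refs`` optionally maps a taxon to (target references,
    contaminant references) for the known-contaminant prescreen.
    ``external_hits`` optionally maps a taxon to precomputed tabular
    hits replacing the builtin search.
    """
    buckets: dict[tuple[str, str], list[Record]] = {}
    audit_rows: list[dict] = []
    ref_by_name = {name: seq for og in og_set for name, seq in og.reference_proteins}

    for taxon in sorted(taxa):
        records = sorted(taxa[taxon])
        if not records:
            logger.warning("taxon %s: empty input", taxon)
            continue
        try:
            pre = prescreen_refs.get(taxon) if prescreen_refs else None
            if pre is not None:
                kept, flagged, no_hit = prescreen_contaminants(
                    records, pre[0], pre[1], config.prescreen_margin, config.min_score,
                    config.params, config.genetic_code,
                )
                for name, _ in flagged:
                    _audit(audit_rows, "prescreen", name, "contaminant_hit", taxon=taxon)
                for name, _ in no_hit:
                    _audit(audit_rows, "prescreen", name, "no_hit", taxon=taxon)
                records = kept

            hits_for_taxon = external_hits.get(taxon) if external_hits else None
            backend = "external-table" if hits_for_taxon is not None else "builtin"
            og_buckets, hits, dropped = assign_to_ogs(
                records, og_set, config.min_score, backend, hits_for_taxon,
                config.params, genetic_code=config.genetic_code,
            )
            for name, reason in dropped:
                _audit(audit_rows, "assign", name, reason, taxon=taxon)

            for og_id in sorted(og_buckets):
                members = og_buckets[og_id]
                translated: list[Record] = []
                for name, seq in members:
                    from .homology import looks_nucleotide

                    if looks_nucleotide(seq):
                        try:
                            (name, prot), report = infer_protein(
                                (name, seq), ref_by_name[hits[name].target],
                                config.genetic_code, config.min_score, config.params,
                            )
                            if report.n_breakpoints:
                                _audit(
                                    audit_rows, "translate", name, "frameshift_recovered",
                                    taxon=taxon, og_id=og_id,
                                    detail=f"breakpoints={report.breakpoints}",
                                )
                            translated.append((name, prot))
                        except (NoFrameError, ProteinInferenceError) as exc:
                            _audit(audit_rows, "translate", name, "rejected", taxon=taxon,
                                   og_id=og_id, detail=str(exc))
                    else:
                        translated.append((name, seq))
                kept, removed = refine_taxon_og(
                    translated, config.id_cutoff, config.sim_cutoff, config.params
                )
                for r in removed:
                    _audit(audit_rows, "refine", r.name, r.reason, taxon=taxon, og_id=og_id,
                           detail=f"partner={r.partner}")
                if kept:
                    buckets[(taxon, og_id)] = kept
        except Exception:
            logger.exception("taxon %s failed; stage continues", taxon)
    audit = pd.DataFrame(audit_rows)
    return TaxonStageResult(buckets, audit)


@dataclass
class GeneStageResult:
    paralog_alignments: dict[str, AlignmentMatrix]
    one_per_taxon: dict[str, AlignmentMatrix]
    trees: dict[str, str]  # og_id -> newick of the screened gene tree
    audit: pd.DataFrame
    failed_ogs: list[str] = field(default_factory=list)


def run_gene_stage(
    taxon_result: TaxonStageResult | dict[str, list[Record]],
    config: PipelineConfig = PipelineConfig(),
    external_trees: Mapping[str, str] | None = None,
) -> GeneStageResult:
    """Per-OG refinement: paralog collapse, confidence alignment,
    tree screen and ortholog selection."""
    og_records = (
        taxon_result.og_records() if isinstance(taxon_result, TaxonStageResult) else taxon_result
    )
    audit_rows: list[dict] = []
    paralog_alignments: dict[str, AlignmentMatrix] = {}
    one_per_taxon: dict[str, AlignmentMatrix] = {}
    trees: dict[str, str] = {}
    failed: list[str] = []

    for i, og_id in enumerate(sorted(og_records)):
        records = sorted(og_records[og_id])
        try:
            if config.drop_ogs_without_taxa:
                from .naming import taxon_prefix

                taxa_present = {taxon_prefix(n) for n, _ in records}
                if not any(t in taxa_present for t in config.drop_ogs_without_taxa):
                    _audit(audit_rows, "gene", og_id, "no_new_taxa", og_id=og_id)
                    continue
            if not config.skip_collapse:
                records, collapsed, _iters = collapse_ingroup_paralogs(
                    records, config.max_iter, config.params
                )
                for c in collapsed:
                    _audit(audit_rows, "collapse", c.name, "ingroup_paralog", og_id=og_id,
                           detail=f"representative={c.representative}")

            try:
                aln, removed_seqs, masked_cols = guidance_filter(
                    records, config.guidance(seed_offset=2 * i)
                )
            except AllSequencesRemoved:
                _audit(audit_rows, "align", og_id, "all_sequences_removed", og_id=og_id)
                failed.append(og_id)
                continue
            for name in removed_seqs:
                _audit(audit_rows, "align", name, "low_sequence_score", og_id=og_id)
            if masked_cols:
                _audit(audit_rows, "align", og_id, "masked_columns", og_id=og_id,
                       detail=f"n={len(masked_cols)}")

            if len(aln.names) >= 3:
                if external_trees and og_id in external_trees:
                    tree = read_newick(external_trees[og_id], is_path=False)
                else:
                    tree = nj_tree(alignment_pdistance(aln.names, aln.rows))
                report = find_misplaced_leaves(tree, config.domains, config.min_neighbors)
                for f in report.flagged:
                    _audit(audit_rows, "screen", f.name, "cross_domain_singleton", og_id=og_id,
                           detail=f"surrounded_by={f.surrounding_domain}")
                if report.flagged_names:
                    aln = aln.drop_rows(report.flagged_names).drop_all_gap_columns()
                    if len(aln.names) >= 3:
                        tree = nj_tree(alignment_pdistance(aln.names, aln.rows))
                trees[og_id] = tree.as_string(schema="newick", unquoted_underscores=True)
            paralog_alignments[og_id] = aln

            if len(aln.names) >= 3 and og_id in trees:
                tree = read_newick(trees[og_id], is_path=False)
                selected, log = select_orthologs(tree, list(zip(aln.names, aln.rows)))
                for d in log:
                    for name in d.discarded:
                        _audit(audit_rows, "select", name, "paralog_not_selected", og_id=og_id,
                               detail=f"kept={d.kept}")
                keep = {n for n, _ in selected}
                one = aln.drop_rows(set(aln.names) - keep).drop_all_gap_columns()
            else:
                one = aln
            one_per_taxon[og_id] = one
        except Exception:
            logger.exception("OG %s failed; stage continues", og_id)
            failed.append(og_id)
    return GeneStageResult(paralog_alignments, one_per_taxon, trees, pd.DataFrame(audit_rows), failed)


def run_concatenation(
    one_per_taxon: Mapping[str, AlignmentMatrix],
    config: PipelineConfig = PipelineConfig(),
    extra_partitions: Sequence[tuple[str, str, AlignmentMatrix]] = (),
    outdir: str | Path | None = None,
) -> tuple[Supermatrix, list[int]]:
    """Concatenate, filter low-occupancy taxa, mask missing-heavy
    columns, and optionally write the supermatrix files."""
    sm = concatenate(dict(one_per_taxon), extra_partitions)
    sm = filter_taxa_min_genes(sm, config.min_genes)
    if not sm.taxa:
        raise RuntimeError(f"no taxon occupies at least {config.min_genes} partitions")
    sm, masked = mask_missing_columns(sm, config.max_missing)
    if outdir is not None:
        write_supermatrix(sm, outdir)
    return sm, masked
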