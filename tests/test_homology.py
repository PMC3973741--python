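import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq

from conftest import mutate, random_protein
from phylopipe.homology import (
    NoFrameError,
    OrthologGroup,
    assign_to_ogs,
    infer_protein,
    prescreen_contaminants,
    read_external_hits,
)
from phylopipe.pairwise import global_align

_CODONS = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)


def reverse_translate(rng, prot):
    return "".join(str(rng.choice(_CODONS[aa])) for aa in prot)


@pytest.fixture
def og_set(rng):
    return [
        OrthologGroup(f"OG_{c}", [(f"OG_{c}_ref{i}", random_protein(rng, 100)) for i in range(2)])
        for c in "ABCDE"
    ]


class TestAssignToOgs:
    def test_self_hit_assigned(self, og_set):
        query = og_set[0].reference_proteins[0][1]
        buckets, hits, dropped = assign_to_ogs([("q", query)], og_set)
        assert list(buckets) == ["OG_A"] and not dropped

    def test_random_query_dropped(self, rng, og_set):
        buckets, hits, dropped = assign_to_ogs(
            [("junk", random_protein(rng, 60))], og_set, min_score=200
        )
        assert dropped == [("junk", "no_hit")] and not buckets

    def test_mutated_queries_recover_generating_og(self, rng, og_set):
        queries, truth = [], {}
        for i in range(20):
            og = og_set[i % 5]
            src = og.reference_proteins[i % 2][1]
            name = f"q{i}"
            queries.append((name, mutate(rng, src, 0.20)))
            truth[name] = og.og_id
        buckets, hits, dropped = assign_to_ogs(queries, og_set)
        assert not dropped
        for og_id, records in buckets.items():
            for name, _ in records:
                assert truth[name] == og_id

    def test_partition_property(self, rng, og_set):
        queries = [(f"q{i}", mutate(rng, og_set[i % 5].reference_proteins[0][1], 0.1)) for i in range(10)]
        buckets, _, _ = assign_to_ogs(queries, og_set)
        seen = [n for records in buckets.values() for n, _ in records]
        assert len(seen) == len(set(seen))

    def test_external_table_backend(self, tmp_path, og_set):
        hits_file = tmp_path / "hits.tsv"
        hits_file.write_text("q1\tOG_B_ref0\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180.0\n")
        target_og = {name: og.og_id for og in og_set for name, _ in og.reference_proteins}
        hits = read_external_hits(hits_file, target_og)
        buckets, _, _ = assign_to_ogs(
            [("q1", "M" * 30)], og_set, backend="external-table", external_hits=hits
        )
        assert list(buckets) == ["OG_B"]

    def test_external_unknown_target_rejected(self, og_set):
        from phylopipe.homology import SearchHit

        bad = [SearchHit("q", "nonexistent_ref", "", 99.0, 0, 1, 50)]
        with pytest.raises(ValueError):
            assign_to_ogs([("q", "M" * 30)], og_set, backend="external-table", external_hits=bad)


class TestPrescreen:
    def test_target_copy_kept_contaminant_copy_flagged(self, rng):
        targets = [("t1", random_protein(rng, 120))]
        contaminants = [("c1", random_protein(rng, 120))]
        kept, flagged, no_hit = prescreen_contaminants(
            [("a", targets[0][1]), ("b", contaminants[0][1])], targets, contaminants
        )
        assert [n for n, _ in kept] == ["a"]
        assert [n for n, _ in flagged] == ["b"]

    def test_divergent_copies_classified(self, rng):
        targets = [("t1", random_protein(rng, 150))]
        contaminants = [("c1", random_protein(rng, 150))]
        records = [(f"t{i}", mutate(rng, targets[0][1], 0.10)) for i in range(10)]
        records += [(f"c{i}", mutate(rng, contaminants[0][1], 0.10)) for i in range(10)]
        kept, flagged, no_hit = prescreen_contaminants(records, targets, contaminants)
        assert {n for n, _ in kept} == {f"t{i}" for i in range(10)}
        assert {n for n, _ in flagged} == {f"c{i}" for i in range(10)}
        assert not no_hit

    def test_unrelated_record_has_no_hit(self, rng):
        kept, flagged, no_hit = prescreen_contaminants(
            [("x", random_protein(rng, 60))],
            [("t", random_protein(rng, 120))],
            [("c", random_protein(rng, 120))],
        )
        assert [n for n, _ in no_hit] == ["x"]


class TestInferProtein:
    def test_clean_cds_translates_exactly(self, rng):
        ref = random_protein(rng, 120)
        cds = reverse_translate(rng, ref) + "TAA"
        (name, prot), report = infer_protein(("q", cds), ref)
        assert prot == ref
        assert report.n_breakpoints == 0

    def test_reverse_complement_gives_same_protein(self, rng):
        ref = random_protein(rng, 100)
        cds = reverse_translate(rng, ref)
        fwd, _ = infer_protein(("q", cds), ref)
        rev, report = infer_protein(("q", str(Seq(cds).reverse_complement())), ref)
        assert fwd[1] == rev[1]
        assert report.strand == -1

    def test_planted_insertion_recovered(self, rng):
        ref = random_protein(rng, 100)
        cds = reverse_translate(rng, ref)
        pos = 3 * 50 + 1
        mut = cds[:pos] + "G" + cds[pos:]
        (name, prot), report = infer_protein(("q", mut), ref)
        res = global_align(prot, ref)
        matches = sum(
            1 for a, b in zip(res.aligned_a, res.aligned_b) if a == b and a != "-"
        )
        assert matches >= 98
        assert report.n_breakpoints == 1
        assert abs(report.breakpoints[0] - 50) <= 2

    def test_no_stop_symbols_in_output(self, rng):
        ref = random_protein(rng, 90)
        cds = reverse_translate(rng, ref)
        mut = cds[:100] + "A" + cds[100:]
        (_, prot), _ = infer_protein(("q", mut), ref)
        assert "*" not in prot

    def test_unrelated_sequence_rejected(self, rng):
        with pytest.raises(NoFrameError):
            infer_protein(("q", reverse_translate(rng, random_protein(rng, 60))),
                          random_protein(rng, 100))

    def test_frameshift_free_equals_naive_translation(self, rng):
        ref = random_protein(rng, 80)
        cds = reverse_translate(rng, ref)
        (_, prot), report = infer_protein(("q", cds), ref)
        naive = str(Seq(cds).translate())
        assert prot == naive
        assert report.n_breakpoints == 0
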