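import numpy as np
import pytest

from conftest import mutate, random_protein
from oracles import pair_support_scores
from phylopipe.confalign import (
    AlignmentMatrix,
    GuidanceConfig,
    base_alignment,
    guidance_filter,
    perturbed_alignments,
    progressive_align,
    residue_pair_scores,
)
from phylopipe.guidetree import nj_tree, pdistance_matrix
from phylopipe.pairwise import global_align


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self, rng):
        seq = random_protein(rng, 60)
        records = [(f"s{i}", seq) for i in range(4)]
        guide = nj_tree(pdistance_matrix(records))
        aln = progressive_align(records, guide)
        assert aln.n_cols == 60
        assert all(row == seq for row in aln.rows)

    def test_two_sequences_match_pairwise(self, rng):
        # a pair with one clear indel has a unique optimum
        base = random_protein(rng, 50)
        a, b = base, base[:20] + base[28:]
        res = global_align(a, b)
        aln = base_alignment([("a", a), ("b", b)])
        assert (aln.rows[0], aln.rows[1]) == (res.aligned_a, res.aligned_b)

    def test_planted_indel_column_count(self, rng):
        base = random_protein(rng, 80)
        records = [(f"s{i}", mutate(rng, base, 0.03)) for i in range(4)]
        withins = base[:40] + random_protein(rng, 6) + base[40:]
        records.append(("s4", withins))
        guide = nj_tree(pdistance_matrix(records))
        aln = progressive_align(records, guide)
        assert aln.n_cols == 86
        assert {n: r.replace("-", "") for n, r in zip(aln.names, aln.rows)} == dict(records)

    def test_guide_mismatch_rejected(self, rng):
        records = [(f"s{i}", random_protein(rng, 30)) for i in range(3)]
        guide = nj_tree(pdistance_matrix([("x", "MKV"), ("y", "MRV"), ("z", "MAV")]))
        with pytest.raises(ValueError):
            progressive_align(records, guide)


class TestPerturbedAlignments:
    def test_reproducible_for_fixed_seed(self, protein_family):
        cfg = GuidanceConfig(n_alternatives=3, seed=42)
        b1, a1 = perturbed_alignments(protein_family, cfg)
        b2, a2 = perturbed_alignments(protein_family, cfg)
        assert b1.rows == b2.rows
        assert all(x.rows == y.rows for x, y in zip(a1, a2))

    def test_identical_inputs_identical_alternatives(self, rng):
        seq = random_protein(rng, 50)
        records = [(f"s{i}", seq) for i in range(5)]
        base, alts = perturbed_alignments(records, GuidanceConfig(n_alternatives=4, seed=1))
        for alt in alts:
            assert alt.rows == base.rows

    def test_alternatives_degap_to_inputs(self, protein_family):
        base, alts = perturbed_alignments(protein_family, GuidanceConfig(n_alternatives=5, seed=3))
        expected = dict(protein_family)
        for alt in alts:
            assert {n: r.replace("-", "") for n, r in zip(alt.names, alt.rows)} == expected


class TestResiduePairScores:
    def test_all_identical_alternatives_score_one(self, protein_family):
        base, _ = perturbed_alignments(protein_family, GuidanceConfig(n_alternatives=3, seed=0))
        scored = residue_pair_scores(base, [base, base, base])
        assert np.allclose(scored.col_scores, 1.0)
        assert all(v == 1.0 for v in scored.seq_scores.values())

    def test_partial_agreement_fraction(self):
        base = AlignmentMatrix(["a", "b"], ["MK", "MK"])
        agree = AlignmentMatrix(["a", "b"], ["MK", "MK"])
        shift = AlignmentMatrix(["a", "b"], ["MK-", "-MK"])
        scored = residue_pair_scores(base, [agree] * 7 + [shift] * 3)
        assert np.allclose(scored.col_scores, [0.7, 0.7])

    def test_matches_bruteforce_oracle(self, rng):
        root = random_protein(rng, 30)
        records = [(f"s{i}", mutate(rng, root, 0.15)) for i in range(6)]
        base, alts = perturbed_alignments(records, GuidanceConfig(n_alternatives=8, seed=9))
        scored = residue_pair_scores(base, alts)
        oracle_cols, oracle_seqs = pair_support_scores(
            base.names, base.rows, [(a.names, a.rows) for a in alts], 8
        )
        assert np.allclose(scored.col_scores, oracle_cols)
        for name in base.names:
            assert scored.seq_scores[name] == pytest.approx(oracle_seqs[name])


class TestGuidanceFilter:
    def test_clean_family_nothing_removed(self, rng):
        seq = random_protein(rng, 70)
        records = [(f"s{i}", seq) for i in range(6)]
        final, removed, masked = guidance_filter(records, GuidanceConfig(seed=4))
        assert not removed and not masked
        assert final.n_cols == 70

    def test_planted_random_sequence_removed_pass1(self, rng, protein_family):
        records = protein_family + [("Op_me_rndz_1", random_protein(rng, 100))]
        final, removed, masked = guidance_filter(records, GuidanceConfig(seed=6))
        assert removed == [records[-1][0]]

    def test_zero_cutoffs_remove_nothing(self, rng, protein_family):
        records = protein_family + [("Op_me_rndx_1", random_protein(rng, 100))]
        final, removed, masked = guidance_filter(
            records, GuidanceConfig(sp_seq_cutoff=0.0, sp_col_cutoff=0.0, seed=6)
        )
        assert not removed and not masked

    def test_masked_columns_monotone_in_cutoff(self, rng):
        root = random_protein(rng, 60)
        records = [(f"s{i}", mutate(rng, root, 0.25)) for i in range(6)]
        counts = []
        for cutoff in (0.2, 0.4, 0.6, 0.8):
            _, _, masked = guidance_filter(
                records, GuidanceConfig(sp_seq_cutoff=0.0, sp_col_cutoff=cutoff, seed=11)
            )
            counts.append(len(masked))
        assert counts == sorted(counts)

    def test_strict_defaults_superset_of_loose(self, rng, protein_family):
        records = protein_family + [("Op_me_rndy_1", random_protein(rng, 100))]
        loose = GuidanceConfig(sp_seq_cutoff=0.5, sp_col_cutoff=0.4, seed=13)
        strict = GuidanceConfig(sp_seq_cutoff=0.6, sp_col_cutoff=0.93, seed=13)
        _, removed_l, masked_l = guidance_filter(records, loose)
        _, removed_s, masked_s = guidance_filter(records, strict)
        assert set(removed_l) <= set(removed_s)
        if set(removed_l) == set(removed_s):
            assert set(masked_l) <= set(masked_s)

    def test_small_families_pass_through(self, rng):
        records = [(f"s{i}", random_protein(rng, 40)) for i in range(3)]
        final, removed, masked = guidance_filter(records, GuidanceConfig(seed=2))
        assert not removed and not masked
        assert sorted(final.names) == ["s0", "s1", "s2"]

    def test_residues_deleted_never_reordered(self, rng):
        root = random_protein(rng, 60)
        records = [(f"s{i}", mutate(rng, root, 0.2)) for i in range(6)]
        final, removed, masked = guidance_filter(records, GuidanceConfig(seed=8))
        originals = dict(records)
        for name, row in zip(final.names, final.rows):
            # surviving residues form a subsequence of the input: deletion
            # by masking only, never reordering
            degapped = row.replace("-", "")
            orig = originals[name]
            i = 0
            for ch in degapped:
                i = orig.find(ch, i)
                assert i != -1
                i += 1
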