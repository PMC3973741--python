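import numpy as np
import pytest

from phylopipe.confalign import AlignmentMatrix
from phylopipe.supermatrix import (
    Partition,
    Supermatrix,
    concatenate,
    filter_taxa_min_genes,
    mask_missing_columns,
    read_phylip,
    write_supermatrix,
)


def aln(names_rows):
    return AlignmentMatrix([n for n, _ in names_rows], [r for _, r in names_rows])


TAXA = [f"Op_me_ta{i:02d}" for i in range(4)]


@pytest.fixture
def two_gene_matrix():
    og1 = aln([(f"{t}_1", "MKVLAHEAGA") for t in TAXA[:3]])
    og2 = aln([(f"{t}_2", "WYRDDEHKLMNPQRS") for t in TAXA[:3]])
    return concatenate({"OG0001": og1, "OG0002": og2})


class TestConcatenate:
    def test_width_and_partitions(self, two_gene_matrix):
        sm = two_gene_matrix
        assert sm.n_cols == 25
        assert [(p.start, p.end) for p in sm.partitions] == [(1, 10), (11, 25)]
        assert all(occ == 2 for occ in sm.occupancy().values())

    def test_absent_taxon_filled_with_missing(self):
        og1 = aln([(f"{TAXA[0]}_1", "MKVL"), (f"{TAXA[1]}_1", "MRVL")])
        og2 = aln([(f"{TAXA[0]}_2", "WYR")])
        sm = concatenate({"OG0001": og1, "OG0002": og2})
        row = dict(zip(sm.taxa, sm.rows))[TAXA[1]]
        assert row[4:] == "---"
        assert sm.occupancy()[TAXA[1]] == 1

    def test_two_sequences_for_one_taxon_rejected(self):
        og = aln([(f"{TAXA[0]}_1", "MKVL"), (f"{TAXA[0]}_2", "MRVL")])
        with pytest.raises(ValueError):
            concatenate({"OG0001": og})

    def test_random_occupancy_bookkeeping(self, rng):
        taxa = [f"Pl_gr_tx{i:02d}" for i in range(30)]
        ogs = {}
        planted = {t: 0 for t in taxa}
        for g in range(40):
            width = int(rng.integers(5, 20))
            rows = []
            for t in taxa:
                if rng.random() < 0.7:
                    rows.append((f"{t}_{g}", "M" * width))
                    planted[t] += 1
            if rows:
                ogs[f"OG{g:04d}"] = aln(rows)
        sm = concatenate(ogs)
        assert sm.n_cols == sum(a.n_cols for a in ogs.values())
        occ = sm.occupancy()
        for t in sm.taxa:
            assert occ[t] == planted[t]

    def test_extra_nt_partition_model_label(self):
        og = aln([(f"{TAXA[0]}_1", "MKVL")])
        ssu = aln([(TAXA[0], "ACGTACGT")])
        sm = concatenate({"OG0001": og}, extra_partitions=[("ssu", "nt", ssu)])
        labels = {p.name: p.model_label for p in sm.partitions}
        assert labels == {"OG0001": "PROTGAMMALG", "ssu": "GTRGAMMA"}


class TestFilters:
    def test_min_gene_threshold_boundary(self, rng):
        taxa = [f"Am_tu_tx{i:02d}" for i in range(3)]
        ogs = {}
        for g in range(21):
            rows = [(f"{taxa[0]}_{g}", "MKVL")]
            if g < 19:
                rows.append((f"{taxa[1]}_{g}", "MRVL"))
            if g < 20:
                rows.append((f"{taxa[2]}_{g}", "MAVL"))
            ogs[f"OG{g:04d}"] = aln(rows)
        sm = concatenate(ogs)
        out = filter_taxa_min_genes(sm, min_genes=20)
        assert set(out.taxa) == {taxa[0], taxa[2]}  # occupancy 19 dropped, 20 kept

    def test_min_genes_zero_is_identity(self, two_gene_matrix):
        out = filter_taxa_min_genes(two_gene_matrix, 0)
        assert out.taxa == two_gene_matrix.taxa and out.rows == two_gene_matrix.rows

    def test_masking_strict_majority_boundary(self):
        rows = [
            ("Op_me_ta00", "M---"),
            ("Op_me_ta01", "M---"),
            ("Op_me_ta02", "MM--"),
            ("Op_me_ta03", "MMM-"),
        ]
        sm = Supermatrix(
            [n for n, _ in rows], [r for _, r in rows], [Partition("g", "aa", 1, 4, "LG")]
        )
        out, masked = mask_missing_columns(sm, 0.5)
        # 0% and exactly-50% columns kept (strict ">"); 75% and 100% deleted
        assert masked == [2, 3]
        assert out.n_cols == 2

    def test_masking_bounds_post_check(self, rng):
        taxa = [f"Sr_di_tx{i:02d}" for i in range(8)]
        width = 50
        rows = []
        for t in taxa:
            rows.append((t, "".join("-" if rng.random() < 0.4 else "K" for _ in range(width))))
        sm = Supermatrix([n for n, _ in rows], [r for _, r in rows],
                         [Partition("g", "aa", 1, width, "LG")])
        out, masked = mask_missing_columns(sm, 0.5)
        arr = np.array([list(r) for r in out.rows])
        assert ((arr == "-").mean(axis=0) <= 0.5).all()
        orig = np.array([list(r) for r in sm.rows])
        for c in masked:
            assert (orig[:, c] == "-").mean() > 0.5

    def test_partition_ranges_recomputed_after_masking(self):
        og1 = aln([("Op_me_ta00_1", "M-VL"), ("Op_me_ta01_1", "M--L")])
        og2 = aln([("Op_me_ta00_2", "WYR")])
        sm = concatenate({"OG0001": og1, "OG0002": og2})
        out, masked = mask_missing_columns(sm, 0.5)
        starts = [p.start for p in out.partitions]
        assert starts[0] == 1
        pos = 1
        for p in sorted(out.partitions, key=lambda p: p.start):
            assert p.start == pos
            pos = p.end + 1
        assert pos - 1 == out.n_cols


class TestWriters:
    def test_phylip_roundtrip_and_partition_file(self, tmp_path, two_gene_matrix):
        paths = write_supermatrix(two_gene_matrix, tmp_path)
        taxa, rows = read_phylip(paths["phylip"])
        assert taxa == two_gene_matrix.taxa and rows == two_gene_matrix.rows
        part = paths["partitions"].read_text()
        assert "LG, OG0001 = 1-10" in part
        assert "LG, OG0002 = 11-25" in part

    def test_nt_partition_written_as_dna_with_model_comment(self, tmp_path):
        og = aln([("Op_me_ta00_1", "MKVL")])
        ssu = aln([("Op_me_ta00", "ACGT")])
        sm = concatenate({"OG0001": og}, extra_partitions=[("ssu", "nt", ssu)])
        paths = write_supermatrix(sm, tmp_path)
        part = paths["partitions"].read_text()
        assert "DNA, ssu = 5-8" in part
        assert "# ssu: GTRGAMMA" in part

    def test_bit_identical_reruns(self, tmp_path, two_gene_matrix):
        p1 = write_supermatrix(two_gene_matrix, tmp_path / "a")
        p2 = write_supermatrix(two_gene_matrix, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
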