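import numpy as np
import pandas as pd
import pytest

import pbscreen as pb
from pbscreen.annotate import (classify_pattern, gene_insertions,
                               relative_positions)
from conftest import make_sites


def cis_row(cis_id="c1", chrom="chr1", apex=120_000, start=115_000,
            end=125_000, best_scale=1_000):
    return pd.DataFrame([{"cis_id": cis_id, "chrom": chrom, "apex_pos": apex,
                          "start": start, "end": end, "best_scale": best_scale}])


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "name", "chrom", "start",
                                       "end", "strand"])


class TestAssociateGenes:
    def test_cis_inside_gene(self):
        genes = genes_df([("g1", "A", "chr1", 100_000, 150_000, "+")])
        out = pb.associate_genes(cis_row(), genes)
        assert out["name"].tolist() == ["A"]
        assert out["flag"].iloc[0] == "overlap"

    def test_two_adjacent_genes_ordered_by_apex_distance(self):
        genes = genes_df([("g1", "A", "chr1", 100_000, 121_000, "+"),
                          ("g2", "B", "chr1", 122_000, 160_000, "+")])
        out = pb.associate_genes(cis_row(apex=124_000), genes)
        # apex 124k: B's midpoint (141k) is 17k away, A's (110.5k) 13.5k away
        assert out["name"].tolist() == ["A", "B"]

    def test_intergenic_without_max_distance(self):
        genes = genes_df([("g1", "A", "chr1", 500_000, 550_000, "+")])
        assert len(pb.associate_genes(cis_row(), genes)) == 0

    def test_nearest_gene_flagged(self):
        genes = genes_df([("g1", "A", "chr1", 500_000, 550_000, "+")])
        out = pb.associate_genes(cis_row(), genes, max_distance=500_000)
        assert out["flag"].tolist() == ["nearest"]


class TestRankCisGenes:
    def _table(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "name": ["W", "X", "Y", "Z"],
            "total_insertions": [12, 30, 12, 5],
            "n_tumors": [10, 20, 8, 5],
        })

    def test_manual_sort_oracle(self):
        ranked = pb.rank_cis_genes(self._table(), {"brain": 46, "spinal": 50})
        # 30 first; the two 12s tie-break by n_tumors (10 > 8); 5 last
        assert ranked["name"].tolist() == ["X", "W", "Y", "Z"]
        assert ranked["rank"].tolist() == [1, 2, 3, 4]

    def test_pct_tumors_against_full_cohort(self):
        ranked = pb.rank_cis_genes(self._table().head(1), {"brain": 46,
                                                           "spinal": 50})
        assert ranked["pct_tumors"].iloc[0] == pytest.approx(100 * 10 / 96)

    def test_zero_cohort_is_parameter_error(self):
        with pytest.raises(pb.ParameterError):
            pb.rank_cis_genes(self._table(), {})


class TestClassifyPattern:
    def test_sense_five_prime_insertions_are_activating(self, toy_gene):
        # 10 sense insertions within the first 10% of the gene body
        ins = make_sites([("S%d" % i, "chr1", 100_000 + 400 * i, "+", "merged", 1)
                          for i in range(10)])
        call = classify_pattern(toy_gene, ins)
        assert call.label == "activating"
        assert call.sense_fraction == 1.0

    def test_scattered_mixed_orientation_is_inactivating(self, toy_gene):
        # 12 insertions across the body, 6 sense / 6 antisense: the
        # gene-trap disruption signature
        ins = make_sites([("S%d" % i, "chr1", 102_000 + 4_000 * i,
                           "+" if i % 2 else "-", "merged", 1)
                          for i in range(12)])
        call = classify_pattern(toy_gene, ins)
        assert call.label == "inactivating"
        assert call.sense_fraction == pytest.approx(0.5)

    def test_single_insertion_is_ambiguous(self, toy_gene):
        ins = make_sites([("S1", "chr1", 100_500, "+", "merged", 1)])
        assert classify_pattern(toy_gene, ins).label == "ambiguous"

    def test_five_sense_upstream_insertions_activate(self, toy_gene):
        ins = make_sites([("S%d" % i, "chr1", 95_000 + 100 * i, "+", "merged", 1)
                          for i in range(5)])
        call = classify_pattern(toy_gene, ins)
        assert call.label == "activating"
        assert call.median_relative_position < 0

    def test_wrong_chromosome_is_input_error(self, toy_gene):
        ins = make_sites([("S1", "chr2", 100_500, "+", "merged", 1)])
        with pytest.raises(pb.InputError):
            classify_pattern(toy_gene, ins)

    @pytest.mark.parametrize("seed", range(8))
    def test_strand_mirror_symmetry(self, seed):
        # reversing coordinates and flipping every strand leaves labels fixed
        rng = np.random.default_rng(seed)
        L = 1_000_000
        start, end = 400_000, 460_000
        gene = {"gene_id": "g", "name": "G", "chrom": "c", "start": start,
                "end": end, "strand": "+"}
        n = int(rng.integers(3, 12))
        pos = rng.integers(start - 5_000, end, n)
        orient = rng.choice(["+", "-"], n)
        ins = make_sites([(f"S{i}", "c", int(pos[i]), orient[i], "merged", 1)
                          for i in range(n)])
        mirror_gene = dict(gene, start=L - end, end=L - start, strand="-")
        flip = {"+": "-", "-": "+"}
        mirror_ins = make_sites([(f"S{i}", "c", int(L - pos[i]),
                                  flip[orient[i]], "merged", 1)
                                 for i in range(n)])
        assert (classify_pattern(gene, ins).label
                == classify_pattern(mirror_gene, mirror_ins).label)


class TestRelativePositions:
    def test_plus_strand(self, toy_gene):
        rel = relative_positions(toy_gene, [100_000, 150_000, 90_000])
        assert rel[0] == pytest.approx(0.0)
        assert rel[1] == pytest.approx(1.0)
        assert rel[2] < 0

    def test_minus_strand_mirrored(self, toy_gene):
        gene = dict(toy_gene, strand="-")
        rel = relative_positions(gene, [150_000, 100_000])
        assert rel[0] == pytest.approx(0.0)
        assert rel[1] == pytest.approx(1.0)


def test_cis_gene_table_tissue_counts_sum(small_screen):
    conf, ttaa, genes, screen = small_screen
    pooled = pb.pool_nonredundant(pb.collapse_reads(screen.insertions))
    params = pb.GkcParams(n_perm=100, alpha=0.05, scales=(10_000, 20_000))
    res = pb.CommonInsertionSiteModel(pooled, ttaa, params=params).fit(seed=2)
    table = pb.build_cis_gene_table(res.cis, pooled, genes)
    assert len(table)
    total = table["brain_insertions"] + table["spinal_insertions"]
    assert (total == table["total_insertions"]).all()
    ranked = pb.rank_cis_genes(table, conf.cohort_sizes)
    assert (ranked["pct_tumors"] <= 100.0).all()
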