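"""TSS CG scans, promoter grids, HCG/ICG/LCG classification."""

import math

import numpy as np
import pandas as pd
import pytest

from methkit import promoters
from methkit.io import GeneModel
from methkit.promoters import BIN_INDICES, PromoterBinGrid

from conftest import make_sites


def grid_from_counts(gene_id, counts):
    bins = pd.DataFrame({
        "bin_index": list(BIN_INDICES),
        "start": np.arange(20) * 200 + 1,
        "end": np.arange(20) * 200 + 200,
        "cg_count": counts,
        "level": np.nan,
        "truncated": False,
    })
    return PromoterBinGrid(gene_id=gene_id, strand="+", bins=bins)


class TestBinTiling:
    def test_plus_strand(self):
        gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
        fa = {"chr1": "A" * 30_000}
        grid = promoters.build_promoter_grid(gene, fa)
        b = grid.bins.set_index("bin_index")
        assert (b.loc[1, "start"], b.loc[1, "end"]) == (10_000, 10_199)
        assert (b.loc[-1, "start"], b.loc[-1, "end"]) == (9_800, 9_999)
        assert (b.loc[10, "end"] - b.loc[-10, "start"] + 1) == 4_000

    def test_minus_strand(self):
        gene = GeneModel("g", "chr1", "-", 2_000, 10_000)
        fa = {"chr1": "A" * 30_000}
        b = promoters.build_promoter_grid(gene, fa).bins.set_index("bin_index")
        assert (b.loc[1, "start"], b.loc[1, "end"]) == (9_801, 10_000)
        assert (b.loc[-1, "start"], b.loc[-1, "end"]) == (10_001, 10_200)

    def test_grid_structure_20_bins_of_200bp(self, study):
        fa = {c: study.genome.sequence(c) for c in study.genome.seqs}
        for gene in study.genome.genes:
            grid = promoters.build_promoter_grid(gene, fa)
            assert len(grid.bins) == 20
            widths = grid.bins["end"] - grid.bins["start"] + 1
            assert (widths == 200).all()
            span = grid.bins["end"].max() - grid.bins["start"].min() + 1
            assert span == 4_000      # contiguous TSS +- 2 kb tiling

    def test_uncovered_bin_has_count_but_no_level(self):
        gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
        fa = {"chr1": "A" * 7_999 + "CG" + "A" * 22_000}  # one CG at 8000
        sites = make_sites([("chr1", 10_050, "CG", 0.4)])
        b = promoters.build_promoter_grid(gene, fa, sites).bins.set_index("bin_index")
        assert b.loc[-10, "cg_count"] == 1 and math.isnan(b.loc[-10, "level"])
        assert b.loc[1, "level"] == pytest.approx(0.4)


class TestTSSScan:
    def test_cg_repeat_sequence_counts_100_per_subregion(self):
        fa = {"chr1": "CG" * 20_000}
        gene = GeneModel("g", "chr1", "+", 20_000, 25_000)
        scans, agg = promoters.tss_scan([gene], fa)
        assert len(agg) == 100
        assert (scans[0].counts == 100).all()

    def test_no_cytosine_counts_zero(self):
        fa = {"chr1": "AT" * 20_000}
        gene = GeneModel("g", "chr1", "+", 20_000, 25_000)
        _, agg = promoters.tss_scan([gene], fa)
        assert np.nansum(agg) == 0

    def test_missing_chromosome_named_in_error(self):
        gene = GeneModel("g", "chrX", "+", 20_000, 25_000)
        with pytest.raises(KeyError, match="chrX"):
            promoters.tss_scan([gene], {"chr1": "ACGT"})

    def test_synthetic_promoters_peak_within_2kb_of_tss(self, study):
        fa = {c: study.genome.sequence(c) for c in study.genome.seqs}
        _, agg = promoters.tss_scan(study.genome.genes, fa)
        assert len(agg) == 100
        # TSS +- 2 kb = subregions 40..59 on the 100-bin axis
        assert int(np.nanargmax(agg)) in range(40, 60)
        assert np.nanmean(agg[40:60]) > 2 * np.nanmean(agg[:20])

    def test_truncated_scan_flagged(self):
        fa = {"chr1": "ACGT" * 3_000}   # 12 kb chromosome
        gene = GeneModel("g", "chr1", "+", 5_000, 9_000)
        scans, _ = promoters.tss_scan([gene], fa)
        assert scans[0].bins["truncated"].any()


class TestClassification:
    @pytest.mark.parametrize("count, label", [
        (1, "LCG"), (2, "LCG"), (3, "LCG"),
        (4, "ICG"), (5, "ICG"), (6, "ICG"), (7, "ICG"), (8, "ICG"),
        (9, "HCG"), (10, "HCG"), (16, "HCG"), (20, "HCG"),
    ])
    def test_boundaries(self, count, label):
        cls = promoters.classify_promoter(grid_from_counts("g", [count] * 20))
        assert cls.label == label
        assert cls.mean_cg_per_bin == pytest.approx(count)

    def test_classes_partition_gene_set(self, study):
        fa = {c: study.genome.sequence(c) for c in study.genome.seqs}
        classes = [promoters.classify_promoter(promoters.build_promoter_grid(g, fa))
                   for g in study.genome.genes]
        labels = [c.label for c in classes]
        assert len(labels) == len(study.genome.genes)
        assert set(labels) <= {"HCG", "ICG", "LCG"}
        # designed classes are recovered exactly from the emitted sequence
        assert {c.gene_id: c.label for c in classes} == study.genome.gene_classes

    def test_cg_count_matches_brute_force(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        fa = {"chr1": seq}
        for _ in range(30):
            s = int(rng.integers(1, 4_800))
            e = s + int(rng.integers(0, 200))
            brute = sum(seq[i:i + 2] == "CG" for i in range(s - 1, min(e, len(seq) - 1)))
            assert promoters.count_cg(fa, "chr1", s, e) == brute


class TestClassProfiles:
    def test_single_gene_per_class_equals_its_grid(self):
        rng = np.random.default_rng(2)
        grids, classes = [], []
        for gid, count in [("h", 12), ("i", 6), ("l", 2)]:
            g = grid_from_counts(gid, [count] * 20)
            g.bins["level"] = rng.random(20)
            grids.append(g)
            classes.append(promoters.classify_promoter(g))
        table, overall = promoters.class_profiles(grids, classes)
        hcg = table[table["promoter_class"] == "HCG"]
        np.testing.assert_allclose(hcg["level"].to_numpy(), grids[0].bins["level"])
        assert overall["HCG"] == pytest.approx(grids[0].bins["level"].mean())

    def test_gene_order_invariance(self, study, dm_sites):
        fa = {c: study.genome.sequence(c) for c in study.genome.seqs}
        grids = [promoters.build_promoter_grid(g, fa, dm_sites)
                 for g in study.genome.genes]
        classes = [promoters.classify_promoter(g) for g in grids]
        t1, o1 = promoters.class_profiles(grids, classes)
        t2, o2 = promoters.class_profiles(grids[::-1], classes[::-1])
        assert o1 == pytest.approx(o2, abs=1e-12)
        pd.testing.assert_frame_equal(
            t1.sort_values(["promoter_class", "bin_index"]).reset_index(drop=True),
            t2.sort_values(["promoter_class", "bin_index"]).reset_index(drop=True),
            atol=1e-12)
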