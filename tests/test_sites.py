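"""Site classification, interval shuffling, permutation enrichment, gene
categorisation, and expression summaries."""

import numpy as np
import pytest
from scipy import stats

from perichrom import simulate, sites
from perichrom.genome import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def refs(layout):
    npc = IntervalSet([GenomicInterval("chrA", 1000, 2000),
                       GenomicInterval("chrA", 10_000, 11_000)], layout=layout)
    nucl = IntervalSet([GenomicInterval("chrA", 5000, 6000),
                        GenomicInterval("chrB", 100, 900)], layout=layout)
    return npc, nucl


class TestClassifySites:
    def test_labels(self, layout, refs):
        npc, nucl = refs
        elys = IntervalSet([
            GenomicInterval("chrA", 1200, 1700),    # NPC only
            GenomicInterval("chrA", 5200, 5400),    # nucl only
            GenomicInterval("chrA", 1900, 5100),    # spans both
            GenomicInterval("chrB", 30_000, 31_000)  # neither
        ], layout=layout)
        out = sites.classify_sites(elys, npc, nucl)
        assert sorted(out["label"]) == sorted(
            ["Elys_NPC", "Elys_nucl", "Elys_NPC/nucl", "unassigned"])

    def test_partition_sums_to_total(self, layout, refs, rng):
        from conftest import random_intervals
        npc, nucl = refs
        elys = random_intervals(rng, layout, 60)
        out = sites.classify_sites(elys, npc, nucl)
        fr = sites.class_fractions(out)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_min_overlap_threshold(self, layout, refs):
        npc, nucl = refs
        elys = IntervalSet([GenomicInterval("chrA", 1990, 2500)], layout=layout)
        assert sites.classify_sites(elys, npc, nucl, min_overlap=1)["label"][0] == "Elys_NPC"
        assert sites.classify_sites(elys, npc, nucl, min_overlap=50)["label"][0] == "unassigned"
        with pytest.raises(ValueError):
            sites.classify_sites(elys, npc, nucl, min_overlap=0)


class TestShuffle:
    def test_lengths_and_chroms_preserved(self, layout, rng):
        from conftest import random_intervals
        ivs = random_intervals(rng, layout, 30)
        shuf = sites.shuffle_intervals(ivs, layout, seed=0, preserve_chrom=True)
        assert sorted(i.length for i in shuf) == sorted(i.length for i in ivs)
        assert sorted(i.chrom for i in shuf) == sorted(i.chrom for i in ivs)

    def test_start_distribution_uniform(self):
        lay = GenomeLayout(("c",), (10,))
        site = IntervalSet([GenomicInterval("c", 0, 1)], layout=lay)
        counts = np.zeros(10)
        for k in range(10_000):
            s = sites.shuffle_intervals(site, lay, seed=k)[0].start
            counts[s] += 1
        p = stats.chisquare(counts)[1]
        assert p > 0.01

    def test_site_longer_than_chromosome(self):
        lay = GenomeLayout(("c",), (10,))
        big = IntervalSet([GenomicInterval("c", 0, 10)], layout=lay)
        # exactly chromosome-length is placeable at one position
        out = sites.shuffle_intervals(big, lay, seed=0)
        assert out[0].start == 0


class TestPermutationTest:
    def test_tiny_exhaustive_case(self):
        # 1-bp site on a 10-bp chromosome, reference [4,7): exactly 3 of
        # 10 placements overlap, so E[null>=1] = 0.3
        lay = GenomeLayout(("c",), (10,))
        q = IntervalSet([GenomicInterval("c", 5, 6)], layout=lay)
        ref = IntervalSet([GenomicInterval("c", 4, 7)], layout=lay)
        res = sites.permutation_overlap_test(q, ref, lay, n_perm=10_000, seed=1)
        assert res.observed == 1
        exact = 0.3
        assert res.p_value == pytest.approx((exact * 10_000 + 1) / 10_001,
                                            abs=0.02)

    def test_maximal_enrichment(self, layout):
        # query identical to a sparse reference: no random placement can
        # beat the observed overlap count, so p = 1/(n_perm + 1)
        ref = IntervalSet([GenomicInterval("chrA", i * 10_000, i * 10_000 + 50)
                           for i in range(9)], layout=layout)
        res = sites.permutation_overlap_test(ref, ref, layout, n_perm=100,
                                             seed=0)
        assert res.observed == 9
        assert res.p_value <= 9 / 101   # few nulls can reach 9 of 9

    def test_reference_whole_genome_gives_p_one(self, layout):
        q = IntervalSet([GenomicInterval("chrA", 100, 200)], layout=layout)
        ref = IntervalSet([GenomicInterval(c, 0, layout.length_of(c))
                           for c in layout.chrom_names], layout=layout)
        res = sites.permutation_overlap_test(q, ref, layout, n_perm=50, seed=0)
        assert res.p_value == 1.0

    def test_human_readable_extreme_p(self, layout):
        ref = IntervalSet([GenomicInterval("chrA", i * 10_000, i * 10_000 + 20)
                           for i in range(10)], layout=layout)
        res = sites.permutation_overlap_test(ref, ref, layout, n_perm=200,
                                             seed=0)
        if (res.null_counts >= res.observed).sum() == 0:
            assert res.human_p().startswith("P <")

    def test_invalid_n_perm(self, layout):
        q = IntervalSet([GenomicInterval("chrA", 0, 10)], layout=layout)
        with pytest.raises(ValueError):
            sites.permutation_overlap_test(q, q, layout, n_perm=0)


class TestOverlapFraction:
    def test_self_overlap_is_100_in_both_modes(self, layout, rng):
        from conftest import random_intervals
        a = random_intervals(rng, layout, 10).merge()
        assert sites.overlap_fraction(a, a, "length") == pytest.approx(100)
        assert sites.overlap_fraction(a, a, "count") == pytest.approx(100)

    def test_half_overlap(self):
        a = IntervalSet([GenomicInterval("c", 0, 100)])
        b = IntervalSet([GenomicInterval("c", 50, 150)])
        assert sites.overlap_fraction(a, b, "length") == pytest.approx(50)
        assert sites.overlap_fraction(a, b, "count") == pytest.approx(100)

    def test_disjoint_and_empty(self):
        a = IntervalSet([GenomicInterval("c", 0, 10)])
        b = IntervalSet([GenomicInterval("c", 50, 60)])
        assert sites.overlap_fraction(a, b) == 0.0
        with pytest.raises(ValueError):
            sites.overlap_fraction(IntervalSet(), b)


class TestFilterInteriorSites:
    def test_interior_kept_boundary_dropped(self, layout):
        lads = IntervalSet([GenomicInterval("chrA", 10_000, 30_000)],
                           layout=layout)
        sites_in = IntervalSet([
            GenomicInterval("chrA", 19_000, 21_000),   # centre 10 kb inside
            GenomicInterval("chrA", 10_500, 11_500),   # centre 1 kb from edge
            GenomicInterval("chrA", 50_000, 51_000),   # outside
        ], layout=layout)
        kept = sites.filter_interior_sites(sites_in, lads, margin=2000)
        assert len(kept) == 1 and kept[0].start == 19_000

    def test_negative_margin_rejected(self, layout):
        with pytest.raises(ValueError):
            sites.filter_interior_sites(IntervalSet(), IntervalSet(), -1)


class TestGeneCategories:
    def test_categories(self, layout, refs):
        npc, nucl = refs
        elys = IntervalSet([
            GenomicInterval("chrA", 1200, 1700),
            GenomicInterval("chrA", 5200, 5400),
            GenomicInterval("chrA", 40_000, 41_000),
        ], layout=layout)
        classes = sites.classify_sites(elys, npc, nucl)
        genes = IntervalSet([
            GenomicInterval("chrA", 1000, 1500, "+", "gNPC"),
            GenomicInterval("chrA", 5000, 5600, "-", "gNucl"),
            GenomicInterval("chrA", 1000, 6000, "+", "gBoth"),
            GenomicInterval("chrA", 80_000, 81_000, "+", "gNone"),
        ], layout=layout)
        out = sites.classify_genes_by_sites(genes, classes)
        cats = dict(zip(out["gene"], out["category"]))
        assert cats == {"gNPC": "NPC_only", "gNucl": "nucl_only",
                        "gBoth": "combination", "gNone": "none"}


class TestTPM:
    def test_single_expressed_gene(self):
        tpm = sites.compute_tpm([10, 0, 0], [100, 100, 100])
        assert tpm[0] == pytest.approx(1e6)

    def test_length_normalisation_ratio(self):
        tpm = sites.compute_tpm([10, 10], [100, 200])
        assert tpm[0] / tpm[1] == pytest.approx(2.0)
        assert tpm[0] == pytest.approx(666_666.666, rel=1e-5)
        assert tpm.sum() == pytest.approx(1e6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sites.compute_tpm([0, 0], [100, 100])


class TestExpressionGroupSummary:
    def test_identical_tables(self):
        tpm = np.array([10.0, 20.0, 5.0, 100.0])
        out = sites.expression_group_summary(tpm, tpm, np.array(["a"] * 4))
        assert out["median_log2fc"].iloc[0] == 0.0
        assert out["wilcoxon_p"].iloc[0] == 1.0

    def test_planted_effect_detected(self):
        sim = simulate.simulate_expression(simulate.ExpressionSimParams(
            n_genes=200, seed=6, planted_log2fc={"NPC_only": 0.5}))
        tpm_ctrl = sites.compute_tpm(sim["control"].sum(1), sim["lengths"])
        tpm_kd = sites.compute_tpm(sim["kd"].sum(1), sim["lengths"])
        out = sites.expression_group_summary(tpm_ctrl, tpm_kd, sim["labels"])
        row = out[out["group"] == "NPC_only"].iloc[0]
        assert row["median_log2fc"] > 0
        assert row["wilcoxon_p"] < 0.01

    def test_null_group_centred(self):
        sim = simulate.simulate_expression(simulate.ExpressionSimParams(
            n_genes=200, seed=8, planted_log2fc={}))
        tpm_ctrl = sites.compute_tpm(sim["control"].sum(1), sim["lengths"])
        tpm_kd = sites.compute_tpm(sim["kd"].sum(1), sim["lengths"])
        out = sites.expression_group_summary(
            tpm_ctrl, tpm_kd, np.array(["all"] * 200))
        assert abs(out["median_log2fc"].iloc[0]) < 0.1

    def test_pseudocount_stabilises_silent_genes(self):
        # both conditions silent: fold change must be exactly zero
        tpm = np.zeros(5)
        out = sites.expression_group_summary(tpm, tpm, np.array(["g"] * 5),
                                             epsilon=1.0)
        assert out["median_log2fc"].iloc[0] == 0.0
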