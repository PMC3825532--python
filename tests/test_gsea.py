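"""Rank scores, gene-set construction, enrichment score and permutation test."""

import numpy as np
import pandas as pd
import pytest

from dmrkit import gsea
from dmrkit.enrichment import FeatureCatalog
from dmrkit.intervals import GeneModel, GenomicInterval


class TestRankScores:
    def test_forced_arithmetic(self):
        table = pd.DataFrame({"p": [0.01, 1.0, 0.001], "logFC": [2.0, -1.0, -0.5]},
                             index=["up", "flat", "down"])
        scores = gsea.rank_scores(table)
        assert scores["up"] == pytest.approx(2.0)
        assert scores["flat"] == pytest.approx(0.0)
        assert scores["down"] == pytest.approx(-3.0)
        assert list(scores.index) == ["up", "flat", "down"]  # descending

    def test_zero_p_capped_with_warning(self):
        table = pd.DataFrame({"p": [0.0], "logFC": [1.0]}, index=["g"])
        with pytest.warns(UserWarning, match="capped"):
            scores = gsea.rank_scores(table)
        assert scores["g"] == pytest.approx(320.0)

    def test_tie_break_by_gene_id(self):
        table = pd.DataFrame({"p": [0.5, 0.5], "logFC": [1, 1]}, index=["b", "a"])
        assert list(gsea.rank_scores(table).index) == ["a", "b"]


class TestEnrichmentScore:
    def test_top_gene_unweighted(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        es, running = gsea.enrichment_score(ranked, {"a"}, weight=0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_full_universe_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError, match="entire universe"):
            gsea.enrichment_score(ranked, {"a", "b"})
        with pytest.raises(ValueError, match="intersect"):
            gsea.enrichment_score(ranked, {"zzz"})

    def test_matches_cumsum_oracle(self):
        rng = np.random.default_rng(17)
        scores = np.sort(rng.normal(0, 2, 50))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(50)])
        members = set(rng.choice(ranked.index, 8, replace=False))
        for weight in (0.0, 1.0):
            es, _ = gsea.enrichment_score(ranked, members, weight=weight)
            hit = ranked.index.isin(members)
            w = np.abs(scores) ** weight
            inc = np.where(hit, w / w[hit].sum(), -1 / (50 - 8))
            running = np.cumsum(inc)
            assert es == pytest.approx(running[np.argmax(np.abs(running))], rel=1e-12)

    def test_es_bounds_and_reversal_negates_at_weight_zero(self):
        rng = np.random.default_rng(18)
        ranked = pd.Series(np.sort(rng.normal(size=40))[::-1],
                           index=[f"g{i}" for i in range(40)])
        members = set(rng.choice(ranked.index, 6, replace=False))
        es, _ = gsea.enrichment_score(ranked, members, weight=0)
        assert -1 <= es <= 1
        reversed_ranked = ranked[::-1]
        es_rev, _ = gsea.enrichment_score(reversed_ranked, members, weight=0)
        assert es_rev == pytest.approx(-es, abs=1e-12)


class TestGeneSets:
    @pytest.fixture()
    def catalog(self):
        genes = [GeneModel("G", "chr1", 10_000, 20_000, "+",
                           exons=((10_000, 11_000), (19_000, 20_000))),
                 GeneModel("H", "chr1", 50_000, 60_000, "+",
                           exons=((50_000, 60_000),))]
        return FeatureCatalog(genes, [], {"chr1": 100_000})

    def test_membership_rules(self, catalog):
        dmrs = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [12_000, 50_500, 12_000],
            "end": [12_100, 50_600, 12_100],
            "logFC": [1.5, -2.0, 1.5],
            "p": [0.005, 0.001, 0.02],  # third fails the cutoff
        })
        with pytest.warns(UserWarning):  # some of the 10 sets are empty
            sets = {s.name: s.members for s in
                    gsea.build_methylation_gene_sets(dmrs.iloc[[0, 2]], catalog)}
        assert sets["intron_increased_methylation"] == {"G"}
        assert "exon_increased_methylation" not in sets  # DMR sits in the intron
        with pytest.warns(UserWarning):
            sets2 = {s.name: s.members for s in
                     gsea.build_methylation_gene_sets(dmrs, catalog)}
        assert sets2["exon_decreased_methylation"] == {"H"}

    def test_membership_matches_all_pairs_oracle(self, toy_genome):
        catalog = FeatureCatalog(list(toy_genome.genes), list(toy_genome.cgis),
                                 toy_genome.chrom_lengths())
        rng = np.random.default_rng(19)
        dmrs = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 150),
            "start": rng.integers(0, 490_000, 150),
            "logFC": rng.normal(size=150),
            "p": rng.random(150) * 0.02,
        })
        dmrs["end"] = dmrs["start"] + rng.integers(50, 2000, 150)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sets = {s.name: s.members for s in
                    gsea.build_methylation_gene_sets(dmrs, catalog)}
        qual = dmrs[dmrs["p"] < 0.01]
        for feature in gsea.GENE_SET_FEATURES:
            for direction, sign in (("increased", 1), ("decreased", -1)):
                sub = qual[np.sign(qual["logFC"]) == sign]
                expected = set()
                for gene, feats in catalog.per_gene.items():
                    for iv in feats[feature]:
                        if any(iv.overlaps(GenomicInterval(r.chrom, r.start, r.end))
                               for r in sub.itertuples(index=False)):
                            expected.add(gene)
                got = sets.get(f"{feature}_{direction}_methylation", set())
                assert got == expected, (feature, direction)

    def test_tf_promoter_sets_size_bounds(self, catalog):
        chip = {"TF1_cell": [GenomicInterval("chr1", 8_000, 9_000)],
                "TF2_cell": [GenomicInterval("chr1", 95_000, 96_000)]}
        sets = gsea.build_promoter_tf_gene_sets(chip, catalog, min_size=1, max_size=10)
        assert {s.name for s in sets} == {"TF1_cell"}
        assert next(iter(sets)).members == frozenset({"G"})
        assert gsea.build_promoter_tf_gene_sets(chip, catalog, min_size=2) == []

    def test_tf_sets_size_filter_arithmetic(self, toy_genome):
        # a catalogue where some tracks are undersized is filtered accordingly
        catalog = FeatureCatalog(list(toy_genome.genes), [], toy_genome.chrom_lengths())
        rng = np.random.default_rng(20)
        promoters = [f["promoter"][0] for f in catalog.per_gene.values()]
        chip = {}
        for i in range(25):
            n_peaks = 1 if i < 5 else 12
            picks = rng.choice(len(promoters), size=n_peaks, replace=False)
            chip[f"TF{i}"] = [promoters[j] for j in picks]
        sets = gsea.build_promoter_tf_gene_sets(chip, catalog, min_size=5, max_size=500)
        assert len(sets) == 20


class TestPermutationTest:
    @staticmethod
    def ranked_universe(seed, n=400):
        rng = np.random.default_rng(seed)
        return pd.Series(np.sort(rng.normal(0, 2, n))[::-1],
                         index=[f"g{i:03d}" for i in range(n)])

    def test_deterministic_for_seed(self):
        ranked = self.ranked_universe(0)
        sets = [gsea.GeneSet("s", frozenset(ranked.index[:20]))]
        t1 = gsea.gsea_preranked(ranked, sets, n_perm=100, seed=5)
        t2 = gsea.gsea_preranked(ranked, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_top_set_significant_random_set_not(self):
        ranked = self.ranked_universe(1)
        rng = np.random.default_rng(2)
        planted = gsea.GeneSet("planted", frozenset(ranked.index[:15]))
        random_set = gsea.GeneSet("random", frozenset(
            rng.choice(ranked.index, 15, replace=False)))
        res = gsea.PrerankedGSEA(ranked, [planted, random_set]).fit(
            n_perm=300, seed=3)
        assert res.table.loc["planted", "es"] > 0
        assert res.table.loc["planted", "fdr_q"] < 0.25
        assert res.table.loc["random", "nominal_p"] > 0.05

    def test_null_nominal_p_calibration(self):
        # 200 random sets against a null ranking: p < 0.05 fraction in [0.02, 0.09]
        ranked = self.ranked_universe(4)
        rng = np.random.default_rng(5)
        sets = [gsea.GeneSet(f"null{i}", frozenset(
            rng.choice(ranked.index, 12, replace=False))) for i in range(200)]
        res = gsea.PrerankedGSEA(ranked, sets).fit(n_perm=200, seed=6)
        frac = (res.table["nominal_p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_single_permutation_degenerate_bounds(self):
        ranked = self.ranked_universe(7)
        sets = [gsea.GeneSet("s", frozenset(ranked.index[:10]))]
        res = gsea.gsea_preranked(ranked, sets, n_perm=1, seed=8)
        assert res["nominal_p"].iloc[0] in (0.5, 1.0)

    def test_monotone_rescaling_invariance_weight_zero(self):
        ranked = self.ranked_universe(9)
        sets = [gsea.GeneSet("s", frozenset(ranked.index[5:25]))]
        r1 = gsea.PrerankedGSEA(ranked, sets, weight=0).fit(100, seed=10).table
        r2 = gsea.PrerankedGSEA(ranked * 7.5, sets, weight=0).fit(100, seed=10).table
        assert r1["nominal_p"].iloc[0] == r2["nominal_p"].iloc[0]
        assert r1["es"].iloc[0] == pytest.approx(r2["es"].iloc[0])
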