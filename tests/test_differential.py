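"""Counting, filtering, TMM, dispersion shrinkage, exact test, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dmrkit import differential as d
from dmrkit.intervals import GenomicInterval


def make_tags(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos5", "strand", "sample"])


class TestCounting:
    def test_basic_and_half_open(self):
        regions = [GenomicInterval("chr1", 100, 200)]
        # shifted positions (shift=0): 3 inside, 1 at end coordinate, 1 outside
        tags = make_tags([("chr1", p, "+", "s") for p in (100, 150, 199, 200, 500)])
        counts = d.count_tags_per_region(regions, tags, shift=0)
        assert counts.iloc[0, 0] == 3

    def test_overlapping_regions_rejected(self):
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        with pytest.raises(ValueError, match="ambiguous"):
            d.count_tags_per_region(regions, make_tags([("chr1", 1, "+", "s")]))

    def test_matches_per_tag_scan_oracle(self):
        rng = np.random.default_rng(4)
        regions = [GenomicInterval("chr1", int(s), int(s) + 200)
                   for s in range(0, 10_000, 500)]
        tags = make_tags([
            ("chr1", int(p), "+" if rng.random() < 0.5 else "-", f"s{rng.integers(2)}")
            for p in rng.integers(0, 10_000, 2000)])
        counts = d.count_tags_per_region(regions, tags, shift=75)
        oracle = pd.DataFrame(0, index=counts.index, columns=counts.columns)
        for t in tags.itertuples(index=False):
            pos = max(0, t.pos5 + (75 if t.strand == "+" else -75))  # clamped
            for iv in regions:
                if iv.start <= pos < iv.end:
                    oracle.loc[f"{iv.chrom}:{iv.start}-{iv.end}", t.sample] += 1
        pd.testing.assert_frame_equal(counts, oracle)


class TestCentileFilter:
    def test_linear_interpolation_definition(self):
        m = pd.DataFrame({"a": [1, 2, 3, 4]}, index=list("wxyz"))
        out = d.centile_filter(m, 50)  # threshold 2.5
        assert list(out.index) == ["y", "z"]

    def test_boundaries_and_ties(self):
        m = pd.DataFrame({"a": [5, 5, 5, 5]})
        assert len(d.centile_filter(m, 50)) == 4  # ties at threshold kept
        assert len(d.centile_filter(m, 0)) == 4
        with pytest.raises(ValueError):
            d.centile_filter(m.iloc[:0], 50)


class TestTMM:
    def test_identical_and_scaled_columns_give_unit_factors(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 500, 800)
        m = pd.DataFrame({"a": a, "b": a, "c": 2 * a})
        f = d.tmm_factors(m)
        assert np.allclose(f, 1.0, atol=1e-6)  # depth is not composition

    def test_composition_bias_detected_and_matches_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.integers(20, 400, 1000)
        b = base.copy()
        b[:50] *= 100  # 5% of rows massively inflated in one sample
        m = pd.DataFrame({"ref": base, "inflated": b})
        f = d.tmm_factors(m)
        # the inflated library's uninflated rows look undersampled: factor < 1
        assert f["inflated"] < 1.0
        # brute-force doubly-trimmed precision-weighted mean oracle
        na, nb = base.sum(), b.sum()
        keep = (base > 0) & (b > 0)
        mvals = np.log2((b[keep] / nb) / (base[keep] / na))
        avals = 0.5 * np.log2((b[keep] / nb) * (base[keep] / na))
        v = (nb - b[keep]) / (nb * b[keep]) + (na - base[keep]) / (na * base[keep])
        n = mvals.size
        order_m = mvals.argsort().argsort() + 1
        order_a = avals.argsort().argsort() + 1
        lo_l, lo_s = int(np.floor(n * 0.3)) + 1, int(np.floor(n * 0.05)) + 1
        sel = ((order_m >= lo_l) & (order_m <= n + 1 - lo_l)
               & (order_a >= lo_s) & (order_a <= n + 1 - lo_s))
        raw = 2.0 ** (np.sum(mvals[sel] / v[sel]) / np.sum(1.0 / v[sel]))
        expected = np.array([1.0, raw])
        expected /= np.exp(np.mean(np.log(expected)))
        assert f["inflated"] == pytest.approx(expected[1], rel=1e-10)

    def test_all_zero_sample_errors(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            d.tmm_factors(m)


class TestDispersion:
    def test_recovers_true_dispersion(self, nb_null_counts):
        counts, groups, phi = nb_null_counts
        est = d.estimate_dispersions(counts, groups)
        assert 0.10 <= est.common <= 0.20  # true 0.15

    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(80, size=(1500, 8)),
                              columns=[f"s{i}" for i in range(8)])
        groups = pd.Series({f"s{i}": "A" if i < 4 else "B" for i in range(8)})
        est = d.estimate_dispersions(counts, groups)
        assert est.common <= 0.05

    def test_infinite_prior_collapses_to_common(self, nb_null_counts):
        counts, groups, _ = nb_null_counts
        est = d.estimate_dispersions(counts, groups, prior_df=1e9)
        assert np.allclose(est.tagwise, est.common, rtol=1e-6)

    def test_no_residual_df_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        groups = pd.Series({"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="fixed dispersion"):
            d.estimate_dispersions(counts, groups)


def binomial_split_oracle(sum_a, sum_b, n_a, n_b):
    """Double-tail binomial oracle for the Poisson-limit exact test."""
    t = sum_a + sum_b
    pmf = stats.binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    return pmf[pmf <= pmf[sum_a] * (1 + 1e-10)].sum()


class TestExactTest:
    def test_identical_groups_null_result(self):
        counts = pd.DataFrame({"a1": [10, 5], "a2": [10, 5],
                               "b1": [10, 5], "b2": [10, 5]})
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = d.nb_exact_test(counts, groups, 0.1, case="B", control="A")
        assert np.allclose(res["logFC"], 0)
        assert np.allclose(res["p"], 1)

    def test_zero_dispersion_matches_binomial_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n_a, n_b = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            t = int(rng.integers(1, 31))
            sum_a = int(rng.integers(0, t + 1))
            got = d._exact_nb_pvalue(sum_a, t - sum_a, n_a, n_b, 0.0)
            assert got == pytest.approx(
                binomial_split_oracle(sum_a, t - sum_a, n_a, n_b), rel=1e-9)

    def test_more_than_two_groups_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
        groups = pd.Series({"a": "A", "b": "B", "c": "C"})
        with pytest.raises(ValueError, match="pairwise"):
            d.nb_exact_test(counts, groups, 0.1)

    def test_null_type_one_error_calibrated(self, nb_null_counts):
        counts, groups, _ = nb_null_counts
        model = d.DifferentialAbundanceModel(counts, groups,
                                             case="PILO", control="CTRL")
        res = model.fit()
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_normalization_invariance_fixed_factors(self, nb_null_counts):
        # counts are equalized to the median effective library, so scaling a
        # sample that stays on the same side of the median is absorbed
        # exactly once the normalization factors are applied
        counts, groups, _ = nb_null_counts
        f1 = d.tmm_factors(counts)
        disp1 = d.estimate_dispersions(counts, groups, f1)
        r1 = d.nb_exact_test(counts, groups, disp1, f1, case="PILO", control="CTRL")
        biggest = (counts.sum(axis=0) * f1).idxmax()
        scaled = counts.copy()
        scaled[biggest] = scaled[biggest] * 3  # rescale one sample's library
        disp2 = d.estimate_dispersions(scaled, groups, f1)
        r2 = d.nb_exact_test(scaled, groups, disp2, f1, case="PILO", control="CTRL")
        assert np.allclose(r1["p"], r2["p"], rtol=1e-12)
        assert np.allclose(r1["logFC"], r2["logFC"], rtol=1e-10, atol=1e-12)

    def test_normalization_invariance_reestimated_factors(self, nb_null_counts):
        # re-estimated TMM factors carry depth-dependent precision weights,
        # so invariance under library rescaling is close but not exact
        counts, groups, _ = nb_null_counts
        f1 = d.tmm_factors(counts)
        disp1 = d.estimate_dispersions(counts, groups, f1)
        r1 = d.nb_exact_test(counts, groups, disp1, f1, case="PILO", control="CTRL")
        biggest = (counts.sum(axis=0) * f1).idxmax()
        scaled = counts.copy()
        scaled[biggest] = scaled[biggest] * 3
        f2 = d.tmm_factors(scaled)
        disp2 = d.estimate_dispersions(scaled, groups, f2)
        r2 = d.nb_exact_test(scaled, groups, disp2, f2, case="PILO", control="CTRL")
        dlog = np.abs(np.log10(r1["p"]) - np.log10(r2["p"]))
        assert dlog.quantile(0.99) <= 0.05
        assert dlog.max() <= 0.3
        assert np.allclose(r1["logFC"], r2["logFC"], atol=0.05)
        assert ((r1["p"] < 0.01) == (r2["p"] < 0.01)).mean() >= 0.99


class TestBH:
    def test_examples(self):
        assert np.allclose(d.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert d.bh_adjust([0.2]) == pytest.approx([0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_dominates_p(self, pvals):
        p = np.asarray(pvals)
        got = d.bh_adjust(p)
        n = p.size
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(n)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            k = n - rank_from_top
            running = min(running, p[idx] * n / k)
            adj[idx] = running
        assert np.allclose(got, adj)
        assert (got >= p - 1e-12).all() and (got <= 1 + 1e-12).all()

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(10)
        p = rng.random(100)
        perm = rng.permutation(100)
        assert np.allclose(d.bh_adjust(p)[perm], d.bh_adjust(p[perm]))


class TestClustering:
    @staticmethod
    def grouped_matrix(seed, n_rows=60, sep=3.0):
        rng = np.random.default_rng(seed)
        cols = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(5)]
        base = rng.normal(0, 1, size=(n_rows, len(cols)))
        base[:, 4:] += sep * rng.choice([-1, 1], size=(n_rows, 1))
        return pd.DataFrame(base, index=[f"r{i}" for i in range(n_rows)],
                            columns=cols)

    def test_top_split_recovers_groups(self):
        m = self.grouped_matrix(0)
        split = d.zscore_cluster(m).column_split()
        a = {split[c] for c in m.columns if c.startswith("A")}
        b = {split[c] for c in m.columns if c.startswith("B")}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_duplicate_columns_zero_distance(self):
        m = self.grouped_matrix(1)
        m["A0_copy"] = m["A0"]
        res = d.zscore_cluster(m)
        z = res.zscores
        assert np.allclose(z["A0"], z["A0_copy"])

    def test_column_order_invariance(self):
        m = self.grouped_matrix(2)
        r1 = d.zscore_cluster(m)
        r2 = d.zscore_cluster(m[list(reversed(m.columns))])
        assert r1.col_order == r2.col_order
        assert r1.row_order == r2.row_order

    def test_constant_rows_dropped_with_warning(self):
        m = self.grouped_matrix(3)
        m.loc["r0"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            res = d.zscore_cluster(m)
        assert "r0" not in res.zscores.index


class TestModelAPI:
    def test_fit_summary_and_cluster(self, nb_null_counts):
        counts, groups, _ = nb_null_counts
        res = d.DifferentialAbundanceModel(
            counts, groups, case="PILO", control="CTRL", centile=30).fit()
        assert {"logFC", "p", "fdr"} <= set(res.table.columns)
        assert (res.table["fdr"] >= res.table["p"] - 1e-12).all()
        text = res.summary()
        assert "common dispersion" in text and "rows tested" in text

    def test_from_dataframe_constructor(self):
        df = pd.DataFrame({"s1": [3, 4, "A"], "s2": [5, 6, "A"],
                           "s3": [1, 2, "B"], "s4": [2, 2, "B"]},
                          index=["r1", "r2", "group"])
        model = d.DifferentialAbundanceModel.from_dataframe(df)
        assert model.counts.shape == (2, 4)
        assert list(model.groups) == ["A", "A", "B", "B"]
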