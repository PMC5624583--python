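"""RPKM, dispersion estimation, NB exact test, FDR and the DEG filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from embex import (
    RnaseqSimConfig,
    adjust_to_common_library,
    bh_fdr,
    deg_filter,
    deg_summary,
    deg_test,
    estimate_tagwise_dispersion,
    fold_difference,
    gen_count_dataset,
    nb_exact_test,
    rpkm,
)

# sensitivity regression floor for planted fold-4 DE at n=3/group, disp 0.1,
# recorded at first implementation
SENSITIVITY_FLOOR = 0.8


def exact_test_oracle(s_a, s_b, n_a, n_b, dispersion):
    """Brute-force conditional exact test via direct combinatorial weights.

    The split of a fixed total between two groups of NB counts with equal
    means follows a negative hypergeometric law with weights
    C(k + n_a/phi - 1, k) * C(s - k + n_b/phi - 1, s - k); dispersion 0 is
    the binomial limit with weights C(s, k) * (n_a/n)**k * (n_b/n)**(s-k).
    Computed with log-gamma arithmetic, independently of the scipy
    distribution machinery used by the implementation.
    """
    s = s_a + s_b
    k = np.arange(s + 1)
    if dispersion == 0:
        logw = (
            gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
            + k * np.log(n_a / (n_a + n_b))
            + (s - k) * np.log(n_b / (n_a + n_b))
        )
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        logw = (
            gammaln(k + r_a) - gammaln(k + 1) - gammaln(r_a)
            + gammaln(s - k + r_b) - gammaln(s - k + 1) - gammaln(r_b)
        )
    w = np.exp(logw - logw.max())
    p_split = w / w.sum()
    return float(p_split[p_split <= p_split[s_a] * (1 + 1e-9)].sum())


class TestRpkm:
    def counts(self, data, genes, samples):
        return pd.DataFrame(data, index=genes, columns=samples)

    def test_unit_case(self):
        c = self.counts([[1]], ["g"], ["s"])
        lengths = pd.Series({"g": 1000})
        lib = pd.Series({"s": 1_000_000})
        assert rpkm(c, lengths, lib).iloc[0, 0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        c = self.counts([[10]], ["g"], ["s"])
        out = rpkm(c, pd.Series({"g": 500}), pd.Series({"s": 2_000_000}))
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_joint_rescaling_invariance_and_linearity(self):
        rng = np.random.default_rng(0)
        c = self.counts(rng.integers(0, 100, (5, 3)), list("abcde"), list("xyz"))
        lengths = pd.Series(rng.integers(200, 2000, 5), index=list("abcde"))
        base = rpkm(c, lengths)
        doubled = rpkm(2 * c, lengths, library_sizes=2 * c.sum(axis=0))
        assert np.allclose(base, doubled)
        scaled = rpkm(3 * c, lengths, library_sizes=c.sum(axis=0))
        assert np.allclose(scaled, 3 * base)

    def test_zero_library_errors(self):
        c = self.counts([[0]], ["g"], ["s"])
        with pytest.raises(ValueError, match="library size"):
            rpkm(c, pd.Series({"g": 1000}))


class TestFoldDifference:
    def test_table_style_ratio(self):
        assert round(fold_difference(19.94, 4.76), 1) == 4.2

    def test_equal_means_give_one(self):
        assert fold_difference(7.7, 7.7) == pytest.approx(1.0)

    def test_zero_denominator_is_infinite(self):
        assert np.isinf(fold_difference(7.86, 0.0))

    def test_zero_over_zero_is_undefined(self):
        assert np.isnan(fold_difference(0.0, 0.0))

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            fold_difference(-1.0, 2.0)


class TestTagwiseDispersion:
    def groups(self, cols):
        return pd.Series(["a"] * (len(cols) // 2) + ["b"] * (len(cols) - len(cols) // 2),
                         index=cols)

    def test_constant_replicates_give_zero(self):
        c = pd.DataFrame(np.full((10, 6), 7), columns=[f"s{i}" for i in range(6)])
        disp = estimate_tagwise_dispersion(c, self.groups(c.columns))
        assert np.allclose(disp, 0.0)

    def test_poisson_counts_concentrate_near_zero(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.poisson(100, (2000, 6)),
                         columns=[f"s{i}" for i in range(6)])
        disp = estimate_tagwise_dispersion(c, self.groups(c.columns))
        assert disp.median() < 0.02

    def test_nb_dispersion_recovered_in_band(self):
        """Median estimate for NB(0.1) counts, 6 per group, lands in [0.05, 0.2]."""
        rng = np.random.default_rng(3)
        r = 1 / 0.1
        mu = 200.0
        c = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), (2000, 12)),
            columns=[f"s{i}" for i in range(12)],
        )
        disp = estimate_tagwise_dispersion(c, self.groups(c.columns))
        assert 0.05 <= disp.median() <= 0.2

    def test_all_zero_gene_gets_zero(self):
        c = pd.DataFrame([[0, 0, 0, 0], [5, 6, 7, 8]],
                         columns=[f"s{i}" for i in range(4)])
        disp = estimate_tagwise_dispersion(c, self.groups(c.columns),
                                           shrink_weight=0.0)
        assert disp.iloc[0] == 0.0


class TestNbExactTest:
    def test_identical_group_sums_give_one(self):
        assert nb_exact_test([5, 5, 5], [5, 5, 5], 0.1) == 1.0

    @pytest.mark.parametrize("dispersion", [0.0, 0.1, 1.0])
    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (3, 3), (2, 3)])
    def test_matches_combinatorial_oracle_small_totals(self, dispersion, n_a, n_b):
        for total in range(0, 16):
            for s_a in range(total + 1):
                a = [s_a] + [0] * (n_a - 1)
                b = [total - s_a] + [0] * (n_b - 1)
                got = nb_exact_test(a, b, dispersion)
                want = exact_test_oracle(s_a, total - s_a, n_a, n_b, dispersion)
                assert got == pytest.approx(want, rel=1e-8), (
                    total, s_a, dispersion, n_a, n_b
                )

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.integers(0, 500, 3)
            b = rng.integers(0, 500, 3)
            p = nb_exact_test(a, b, float(rng.uniform(0, 1)))
            assert 0 < p <= 1

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1, 2], [3, 4], 0.1)

    def test_extreme_split_is_significant(self):
        assert nb_exact_test([500, 480, 510], [50, 55, 45], 0.01) < 1e-6


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_naive_step_up(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        # naive BH: sort, scale by m/rank, enforce monotonicity from the top
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(bh_fdr(p), expected)


def table2_records():
    """DHN1-style per-day records with the published RPKM means and p-values."""
    rows = [
        (3, 19.94, 4.76, 6.13e-8),
        (7, 17.88, 3.49, 6.42e-6),
        (15, 19.36, 2.87, 7.03e-10),
        (21, 40.39, 2.02, 8.94e-20),
    ]
    return pd.DataFrame(
        [
            {
                "gene": "DHN1",
                "day": d,
                "mean_rpkm_responsive": r,
                "mean_rpkm_nonresponsive": n,
                "fold_difference": fold_difference(r, n),
                "p_value": p,
                "fdr": p,
            }
            for d, r, n, p in rows
        ]
    )


class TestDegFilter:
    def test_dhn1_rows_all_retained_responsive(self):
        out = deg_filter(table2_records())
        assert len(out) == 4
        assert (out["induced_phenotype"] == "responsive").all()

    def test_small_fold_dropped(self):
        rec = table2_records().head(1).assign(fold_difference=1.5, p_value=0.001,
                                              fdr=0.001)
        assert len(deg_filter(rec)) == 0

    def test_reciprocal_fold_retained_as_nonresponsive(self):
        rec = table2_records().head(1).assign(fold_difference=0.4, p_value=0.01,
                                              fdr=0.01)
        out = deg_filter(rec)
        assert len(out) == 1
        assert out["induced_phenotype"].iloc[0] == "nonresponsive"

    def test_infinite_fold_is_responsive_induced(self):
        rec = table2_records().head(1).assign(fold_difference=np.inf)
        assert deg_filter(rec)["induced_phenotype"].iloc[0] == "responsive"

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(7)
        rec = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "day": 3,
                "mean_rpkm_responsive": rng.uniform(0, 50, 200),
                "mean_rpkm_nonresponsive": rng.uniform(0, 50, 200),
                "fold_difference": rng.lognormal(0, 1.5, 200),
                "p_value": rng.uniform(0, 1, 200),
                "fdr": rng.uniform(0, 1, 200),
            }
        )
        for use_fdr in (True, False):
            n_by_p = [
                len(deg_filter(rec, p_threshold=p, use_fdr=use_fdr))
                for p in (0.2, 0.1, 0.05, 0.01)
            ]
            assert n_by_p == sorted(n_by_p, reverse=True)
            n_by_fold = [
                len(deg_filter(rec, fold_threshold=f, use_fdr=use_fdr))
                for f in (1.5, 2.0, 3.0, 5.0)
            ]
            assert n_by_fold == sorted(n_by_fold, reverse=True)

    def test_raw_p_flag(self):
        rec = table2_records().head(1).assign(p_value=0.01, fdr=0.2)
        assert len(deg_filter(rec, use_fdr=True)) == 0
        assert len(deg_filter(rec, use_fdr=False)) == 1


class TestDegSummary:
    def test_empty_records_give_empty_summary(self):
        out = deg_summary(deg_filter(table2_records(), p_threshold=1e-30))
        assert (out["n_deg"] == 0).all() if len(out) else True

    def test_singleton_mean(self):
        out = deg_summary(deg_filter(table2_records().head(1)))
        row = out[(out["day"] == 3) & (out["induced_phenotype"] == "responsive")]
        assert row["n_deg"].iloc[0] == 1
        assert row["average_rpkm"].iloc[0] == pytest.approx(19.94)

    def test_planted_de_recovery(self):
        """>=80% of planted fold-4 DE genes at n=3/group pass the filter."""
        config = RnaseqSimConfig(
            n_genes=300, de_fraction=1 / 30, fold_range=(4.0, 4.0),
            days=(3.0,), library_size_range=(30_000, 60_000), seed=9,
        )
        counts, sheet, lengths, truth = gen_count_dataset(config)
        records = deg_test(counts, sheet, lengths)
        filtered = deg_filter(records)
        de_genes = set(truth.de_labels.index[truth.de_labels["is_de"]])
        hits = set(filtered["gene"]) & de_genes
        assert len(hits) / len(de_genes) >= SENSITIVITY_FLOOR
        # induced direction matches the planted group
        for gene in hits:
            planted = truth.de_labels.loc[gene, "induced_group"]
            called = filtered.loc[filtered["gene"] == gene,
                                  "induced_phenotype"].iloc[0]
            assert called == planted


class TestDegTestIntegration:
    def test_records_shape_and_ranges(self):
        config = RnaseqSimConfig(n_genes=50, days=(3.0, 7.0),
                                 library_size_range=(10_000, 20_000), seed=11)
        counts, sheet, lengths, _ = gen_count_dataset(config)
        records = deg_test(counts, sheet, lengths)
        assert len(records) == 50 * 2
        assert records["p_value"].between(0, 1).all()
        assert records["fdr"].between(0, 1).all()
        assert (records["fdr"] >= records["p_value"] - 1e-12).all()

    def test_too_few_replicates_error(self):
        config = RnaseqSimConfig(n_genes=10, n_replicates=1, days=(3.0,),
                                 library_size_range=(5_000, 10_000), seed=1)
        counts, sheet, lengths, _ = gen_count_dataset(config)
        with pytest.raises(ValueError, match="need >=2 samples"):
            deg_test(counts, sheet, lengths)

    def test_common_library_adjustment_equalizes_totals(self):
        rng = np.random.default_rng(13)
        c = pd.DataFrame(rng.poisson([100, 300, 900], (50, 3)),
                         columns=list("xyz"))
        adj = adjust_to_common_library(c)
        totals = adj.sum(axis=0)
        assert totals.max() / totals.min() < 1.2
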