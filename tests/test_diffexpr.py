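"""Differential expression: filtering, normalization, NB Wald, shrinkage,
chromosome enrichment — each against hand-computable or simulated oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trisomics.diffexpr import (
    NegativeBinomialDE, chromosome_enrichment, nb_wald_test, prefilter_genes,
    shrink_lfc, size_factors, _pearson_chi2,
)


def _samples(n_ds, n_ctrl, sexes=None):
    ids = [f"D{i}" for i in range(n_ds)] + [f"C{i}" for i in range(n_ctrl)]
    cond = ["DS"] * n_ds + ["control"] * n_ctrl
    if sexes is None:
        sexes = ["F", "M"] * ((n_ds + n_ctrl) // 2 + 1)
    return pd.DataFrame({"condition": cond, "sex": sexes[:len(ids)]}, index=ids)


class TestPrefilter:
    @pytest.mark.parametrize("counts,kept", [
        ([12, 11, 10, 10, 0, 0, 0, 0, 0], True),
        ([9, 9, 9, 9, 9, 9, 9, 9, 9], False),
        ([0] * 9, False),
    ])
    def test_ten_counts_in_four_samples(self, counts, kept):
        m = pd.DataFrame([counts], index=["g"])
        assert ("g" in prefilter_genes(m)) is kept


class TestSizeFactors:
    def test_doubled_sample(self):
        a = np.array([10, 100, 40, 7], dtype=float)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 8, 2], "s2": [5, 8, 2], "s3": [5, 8, 2]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scale_equivariance(self, rng):
        # scaling one sample by c scales its factor by c relative to the
        # others (median-of-ratios factors are defined up to a common scale:
        # the geometric-mean reference moves by c^(1/n))
        counts = pd.DataFrame(rng.integers(1, 200, size=(30, 4)))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled[2] = counts[2] * 3
        sf2 = size_factors(scaled)
        assert sf2[2] / sf2[0] == pytest.approx(3 * sf[2] / sf[0])
        assert sf2[1] / sf2[0] == pytest.approx(sf[1] / sf[0])

    def test_all_zero_gene_rows_error(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)

    def test_matches_pydeseq2(self, rng):
        counts = pd.DataFrame(rng.integers(5, 500, size=(60, 8)),
                              index=[f"g{i}" for i in range(60)],
                              columns=[f"s{i}" for i in range(8)])
        from pydeseq2.preprocessing import deseq2_norm
        _, expected = deseq2_norm(counts.T)
        got = size_factors(counts)
        assert np.allclose(got.to_numpy(), np.asarray(expected), rtol=1e-10)


class TestNbWald:
    def test_exact_fold_change_in_low_dispersion_limit(self):
        # DS counts exactly 4x control, equal size factors, no sex signal
        samples = _samples(4, 4)
        counts = pd.DataFrame(
            [[400] * 4 + [100] * 4, [1000] * 8, [220] * 8, [70] * 8, [510] * 8],
            index=list("abcde"), columns=samples.index)
        sf = pd.Series(1.0, index=samples.index)
        res = nb_wald_test(counts, sf, samples)
        assert res.loc["a", "log2fc"] == pytest.approx(2.0, abs=1e-4)
        assert res.loc["b", "log2fc"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_two_group_ratio(self, rng):
        # In the pure 2-group fit with equal offsets the NB score equations
        # are solved exactly by the group arithmetic means, so the contrast
        # equals the plain log-ratio of group means for any dispersion; a
        # balanced orthogonal sex covariate perturbs it only slightly.
        samples = _samples(4, 4, sexes=["F"] * 8)
        counts = pd.DataFrame(rng.negative_binomial(20, 0.1, size=(40, 8)) + 1,
                              columns=samples.index)
        sf = pd.Series(1.0, index=samples.index)
        res = nb_wald_test(counts, sf, samples)
        ratio = np.log2(counts.loc[:, samples["condition"] == "DS"].mean(axis=1)
                        / counts.loc[:, samples["condition"] == "control"].mean(axis=1))
        assert np.allclose(res["log2fc"], ratio, atol=1e-8)
        samples2 = _samples(4, 4, sexes=["F", "F", "M", "M"] * 2)
        res2 = nb_wald_test(counts, sf, samples2)
        assert np.allclose(res2["log2fc"], ratio, atol=0.15)

    def test_planted_lfc_recovered_with_small_bias(self):
        from trisomics import simulate_study
        st = simulate_study(n_planted_de=60, nb_dispersion=0.05, seed=77,
                            n_contaminant_samples=0, n_outlier_samples=0)
        res = NegativeBinomialDE.from_study(st).fit()
        truth = st.truth["de_genes"].query("kind == 'planted'").set_index("gene_id")
        est = res.table.loc[truth.index, "log2fc"]
        bias = (est - truth["true_log2fc"]).mean()
        assert abs(bias) < 0.1

    def test_requires_two_samples_per_condition(self):
        samples = _samples(1, 3)
        counts = pd.DataFrame([[5, 5, 5, 5]], columns=samples.index)
        with pytest.raises(ValueError, match="DS"):
            nb_wald_test(counts, pd.Series(1.0, index=samples.index), samples)


class TestBenjaminiHochberg:
    def test_agrees_with_textbook_step_up(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 50))
            got = multipletests(p, method="fdr_bh")[1]
            # direct sort-based step-up definition
            n = len(p)
            order = np.argsort(p)
            ranked = p[order] * n / np.arange(1, n + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            expect = np.empty(n)
            expect[order] = np.minimum(adj, 1.0)
            assert np.allclose(got, expect, atol=1e-10)


class TestShrinkage:
    def test_zero_se_keeps_raw_value(self):
        de = pd.DataFrame({"log2fc": [2.0, -1.0, 0.5, 0.1, -0.2],
                           "se": [0.0, 0.5, 0.5, 0.4, 0.3]})
        s = shrink_lfc(de)
        assert s.iloc[0] == pytest.approx(2.0)

    def test_contraction_property(self, rng):
        de = pd.DataFrame({"log2fc": rng.normal(0, 1, 100),
                           "se": rng.uniform(0.1, 1.0, 100)})
        s = shrink_lfc(de)
        assert (s.abs() <= de["log2fc"].abs() + 1e-12).all()

    def test_pure_noise_shrinks_heavily(self, rng):
        # when the marginal spread equals the noise, tau2 -> 0 and estimates
        # collapse toward zero (fallback keeps tau2 positive)
        se = np.full(200, 0.5)
        de = pd.DataFrame({"log2fc": rng.normal(0, 0.5, 200), "se": se})
        s = shrink_lfc(de)
        assert s.abs().mean() < 0.6 * de["log2fc"].abs().mean()


class TestChromosomeEnrichment:
    def test_two_by_two_matches_direct_formula(self):
        table = np.array([[30, 70], [100, 900]])
        chi2, p, df = _pearson_chi2(table)
        # hand-computed sum of (O-E)^2/E
        expect = 0.0
        rows, cols, total = table.sum(1), table.sum(0), table.sum()
        for i in range(2):
            for j in range(2):
                e = rows[i] * cols[j] / total
                expect += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(expect, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expect, 1), abs=1e-12)
        # cross-check against scipy's Pearson statistic, correction off
        s_chi2, s_p, s_df, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(s_chi2, abs=1e-10)

    def test_uniformity_p_uniform_under_random_degs(self, rng):
        # DEGs drawn uniformly from expressed genes -> goodness-of-fit p
        # should be uniform over replicates (KS check)
        chroms = np.repeat([f"chr{i}" for i in range(1, 11)], 100)
        pvals = []
        for _ in range(400):
            deg = rng.random(len(chroms)) < 0.08
            de = pd.DataFrame({
                "p": 0.5, "fdr": np.where(deg, 0.01, 0.5),
                "log2fc": rng.normal(size=len(chroms)), "chrom": chroms})
            pvals.append(chromosome_enrichment(de)["uniformity"]["p"])
        ks = stats.kstest(pvals, "uniform")
        # the chi-squared approximation on counts makes p only approximately
        # uniform: bound the KS distance and the tail mass instead
        assert ks.statistic < 0.1
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_empty_deg_set_returns_flat_results(self):
        de = pd.DataFrame({"p": [0.5, 0.9], "fdr": [0.5, 0.9],
                           "log2fc": [0.1, -0.1], "chrom": ["chr1", "chr2"]})
        res = chromosome_enrichment(de)
        assert res["chr21"]["p"] == 1.0 and "warning" in res

    def test_default_trisomy_study_enriched_for_chr21(self, de_results):
        res = de_results.chromosome_enrichment()
        assert res["chr21"]["p"] < 0.05
        # chr21 DEGs are overexpressed
        sig = de_results.significant
        on21 = sig[sig["chrom"] == "chr21"]
        assert (on21["log2fc"] > 0).all()


def test_mean_fold_change_reflects_dosage(clean_study, de_results):
    truth = clean_study.truth["de_genes"]
    aff = set(truth.loc[truth["kind"] == "chr21_dosage", "gene_id"])
    sig = de_results.significant
    rec = [g for g in sig.index if g in aff]
    mean_fc = float(np.mean(2.0 ** sig.loc[rec, "log2fc"]))
    assert mean_fc == pytest.approx(1.5, abs=0.15)
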