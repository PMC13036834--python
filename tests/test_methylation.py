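"""Differential methylation: probe filter, beta/M, DMP OLS, surrogate
variables, bump-hunting candidate logic and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trisomics.methylation import (
    beta_to_m, dmp_test, estimate_surrogate, filter_probes, find_dmrs,
    m_to_beta, _cluster_positions, _find_candidates, _running_mean_within,
)
from tests.conftest import planted_dmr_recovery


def _cpg_ann(n, chrom="chr1", start=1000, gap=100, **flags):
    d = {"chrom": chrom, "position": start + gap * np.arange(n),
         "flag_allosomal": False, "flag_chr21": False,
         "flag_polymorphic": False, "flag_crossreactive": False}
    d.update(flags)
    return pd.DataFrame(d, index=[f"cg{i}" for i in range(n)])


def _samples(n_ds=3, n_ctrl=3):
    ids = [f"D{i}" for i in range(n_ds)] + [f"C{i}" for i in range(n_ctrl)]
    return pd.DataFrame({"condition": ["DS"] * n_ds + ["control"] * n_ctrl,
                         "sex": (["F", "M"] * ((n_ds + n_ctrl) // 2 + 1))[:len(ids)]},
                        index=ids)


class TestFilterProbes:
    def test_each_flag_drops_and_clean_kept(self):
        ann = _cpg_ann(10)
        for i, flag in enumerate(["flag_allosomal", "flag_chr21",
                                  "flag_polymorphic", "flag_crossreactive"]):
            ann.loc[f"cg{i}", flag] = True
        betas = pd.DataFrame(0.5, index=ann.index, columns=["s1", "s2"])
        kept = filter_probes(betas, ann)
        assert len(kept) == 6
        assert set(kept) == {f"cg{i}" for i in range(4, 10)}

    def test_missing_annotation_is_error(self):
        ann = _cpg_ann(2)
        betas = pd.DataFrame(0.5, index=["cg0", "cg1", "cgX"], columns=["s"])
        with pytest.raises(ValueError, match="cgX"):
            filter_probes(betas, ann)


class TestBetaM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_logit2_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m)

    def test_round_trip(self, rng):
        b = rng.uniform(1e-5, 1 - 1e-5, 100)
        assert np.allclose(m_to_beta(beta_to_m(b)), b, atol=1e-12)


class TestDmpTest:
    def test_matches_hand_normal_equations(self, rng):
        samples = _samples()
        betas = pd.DataFrame(rng.uniform(0.2, 0.8, size=(4, 6)),
                             columns=samples.index)
        M = beta_to_m(betas)
        res = dmp_test(M, betas, samples)
        X = np.column_stack([np.ones(6),
                             (samples["condition"] == "DS").astype(float),
                             (samples["sex"] == "M").astype(float)])
        for i in range(4):
            y = M.iloc[i].to_numpy()
            beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta_hat
            s2 = resid @ resid / (6 - 3)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta_hat[1] / se
            assert res["t_stat"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert res["p"].iloc[i] == pytest.approx(2 * stats.t.sf(abs(t), 3),
                                                     abs=1e-12)

    def test_exact_group_shift_with_zero_noise(self):
        samples = _samples()
        base = np.full(6, 0.4)
        shift = np.array([0.2, 0.2, 0.2, 0.0, 0.0, 0.0])
        betas = pd.DataFrame([base + shift, base], index=["cgA", "cgB"],
                             columns=samples.index)
        # tiny jitter so the regression is not exactly singular in variance
        res = dmp_test(beta_to_m(betas), betas, samples)
        assert res.loc["cgA", "delta_beta"] == pytest.approx(0.2)
        assert res.loc["cgA", "p"] < 1e-10

    def test_type_one_error_under_null(self):
        from trisomics import simulate_study
        st = simulate_study(n_genes=300, n_chr21_genes=20, n_cpgs=2000,
                            dosage_factor=1.0, n_planted_de=0,
                            n_planted_dmrs=0, n_cis_effects=0,
                            n_contaminant_samples=0, n_outlier_samples=0,
                            seed=55)
        kept = filter_probes(st.betas, st.cpg_annotation)
        b = st.betas.loc[kept]
        M = beta_to_m(b)
        sv = estimate_surrogate(M, st.samples, 1)
        res = dmp_test(M, b, st.samples, sv)
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestSurrogate:
    def test_recovers_planted_batch(self):
        from trisomics import simulate_study
        st = simulate_study(batch_effect_sd=0.9, beta_noise_sd=0.3, seed=42,
                            n_contaminant_samples=0, n_outlier_samples=0)
        M = beta_to_m(st.betas)
        sv = estimate_surrogate(M, st.samples, 1)
        batch = (st.samples["batch"] == 1).astype(float)
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) > 0.9

    def test_orthogonal_to_nuisance_columns(self, rng):
        samples = _samples(4, 4)
        M = pd.DataFrame(rng.normal(size=(50, 8)), columns=samples.index)
        sv = estimate_surrogate(M, samples, 2)
        sex = (samples["sex"] == "M").astype(float).to_numpy()
        for j in range(2):
            assert abs(sv[:, j].sum()) < 1e-8
            assert abs(sv[:, j] @ (sex - sex.mean())) < 1e-8

    def test_too_many_surrogates_raise(self, rng):
        samples = _samples(2, 2)
        M = pd.DataFrame(rng.normal(size=(10, 4)), columns=samples.index)
        with pytest.raises(ValueError, match="n_sv"):
            estimate_surrogate(M, samples, 3)


class TestCandidateRegions:
    def test_hand_summed_area(self):
        sm = np.array([0.08, 0.07, 0.06])
        cands = _find_candidates(sm, np.zeros(3, dtype=int), 0.05, 3)
        assert len(cands) == 1
        i, j, area = cands[0]
        assert (i, j) == (0, 2)
        assert area == pytest.approx(0.21)

    def test_sign_flip_breaks_run(self):
        sm = np.array([0.08, -0.07, 0.06])
        assert _find_candidates(sm, np.zeros(3, dtype=int), 0.05, 3) == []

    def test_cluster_boundary_breaks_run(self):
        sm = np.array([0.08, 0.08, 0.08, 0.08])
        cluster = np.array([0, 0, 1, 1])
        cands = _find_candidates(sm, cluster, 0.05, 3)
        assert cands == []

    def test_below_cutoff_excluded(self):
        sm = np.array([0.08, 0.04, 0.08, 0.09, 0.06])
        cands = _find_candidates(sm, np.zeros(5, dtype=int), 0.05, 3)
        assert len(cands) == 1
        assert cands[0][:2] == (2, 4)

    def test_clustering_by_gap_and_chromosome(self):
        chrom = np.array(["chr1", "chr1", "chr1", "chr2"])
        pos = np.array([100, 500, 1200, 100])
        cl = _cluster_positions(chrom, pos, maxgap=500)
        assert list(cl) == [0, 0, 1, 2]

    def test_running_mean_window3(self):
        v = np.array([1.0, 2.0, 3.0, 10.0])
        cl = np.array([0, 0, 0, 1])
        out = _running_mean_within(v, cl, 3)
        assert np.allclose(out, [1.5, 2.0, 2.5, 10.0])


class TestFindDmrs:
    def test_region_boundaries_and_delta_beta_consistency(self, default_study):
        st = default_study
        kept = [s for s in st.counts.columns
                if s not in set(st.truth["samples"]["sample_id"])]
        retained = filter_probes(st.betas[kept], st.cpg_annotation)
        tab = find_dmrs(st.betas.loc[retained, kept], st.samples,
                        st.cpg_annotation, n_perm=20, seed=3)
        assert len(tab) > 0
        ann = st.cpg_annotation
        is_ds = (st.samples.loc[kept, "condition"] == "DS").to_numpy()
        for _, r in tab.iterrows():
            probes = r["probe_ids"].split(";")
            positions = ann.loc[probes, "position"]
            assert r["start"] == positions.min()
            assert r["end"] == positions.max()
            assert r["n_cpgs"] >= 3
            assert (np.diff(np.sort(positions)) <= 500).all()
            assert r["area"] >= r["n_cpgs"] * 0.05 - 1e-12
            b = st.betas.loc[probes, kept]
            delta = (b.loc[:, is_ds].mean(axis=1)
                     - b.loc[:, ~is_ds].mean(axis=1)).mean()
            assert r["mean_delta_beta"] == pytest.approx(delta, abs=1e-12)

    def test_planted_dmrs_recovered(self, default_study):
        st = default_study
        kept = [s for s in st.counts.columns
                if s not in set(st.truth["samples"]["sample_id"])]
        retained = filter_probes(st.betas[kept], st.cpg_annotation)
        tab = find_dmrs(st.betas.loc[retained, kept], st.samples,
                        st.cpg_annotation, n_perm=100, seed=3)
        found, total = planted_dmr_recovery(st, tab)
        assert found / total >= 0.8

    def test_null_study_yields_no_dmrs(self, null_study):
        st = null_study
        retained = filter_probes(st.betas, st.cpg_annotation)
        tab = find_dmrs(st.betas.loc[retained], st.samples, st.cpg_annotation,
                        n_perm=50, seed=3)
        assert len(tab) == 0 or (tab["fdr"] < 0.01).sum() == 0

    def test_low_n_perm_warns(self, null_study):
        st = null_study
        retained = filter_probes(st.betas, st.cpg_annotation)[:200]
        with pytest.warns(UserWarning, match="n_perm"):
            find_dmrs(st.betas.loc[retained], st.samples, st.cpg_annotation,
                      n_perm=5, seed=1)
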