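"""Mixed-model association, weighted significance, credible sets, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from vocalgwas.assoc import (
    SignificanceWeights,
    coloc_overlap,
    credible_set,
    effect_in_hz,
    is_significant,
    ld_r2,
    wakefield_abf,
)
from vocalgwas.mixedlm import KinshipError, KinshipMixedLM
from vocalgwas.simulate import _pedigree_kinship


class TestMixedModel:
    def test_identity_kinship_equals_ols(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.4 * X[:, 1] + rng.normal(size=n)
        g = rng.binomial(2, 0.3, n).astype(float)
        fit = KinshipMixedLM(y, X, np.eye(n)).fit()
        res = fit.test_variant(g)
        ols = sm.OLS(y, np.column_stack([X, g])).fit()
        assert res.beta == pytest.approx(ols.params[-1], rel=1e-8)
        assert res.se == pytest.approx(ols.bse[-1], rel=1e-8)
        assert res.p == pytest.approx(ols.pvalues[-1], rel=1e-6)

    def test_no_genetic_variance_estimates_near_zero(self, rng):
        n = 400
        K = _pedigree_kinship(n, "sibpairs")
        y = rng.normal(size=n)  # independent of kinship
        fit = KinshipMixedLM(y, None, K).fit()
        assert fit.h2 < 0.15

    def test_sibpair_variance_recovery(self, rng):
        n = 600
        K = _pedigree_kinship(n, "sibpairs")
        lam, U = np.linalg.eigh(K)
        h2_hat = []
        true_h2 = 0.5
        for _ in range(30):
            u = U @ (np.sqrt(lam) * rng.normal(size=n))  # N(0, K); var 0.5
            y = np.sqrt(true_h2) * u / np.sqrt(0.5) \
                + np.sqrt(1 - true_h2) * rng.normal(size=n)
            fit = KinshipMixedLM(y, None, K, eig=(lam, U)).fit()
            var_g = fit.sigma_g2 * 0.5  # diag(K) = 0.5
            h2_hat.append(var_g / (var_g + fit.sigma_e2))
        mc_se = np.std(h2_hat) / np.sqrt(len(h2_hat))
        assert abs(np.mean(h2_hat) - true_h2) < 2 * mc_se + 0.02

    def test_null_p_values_uniform(self, rng):
        n = 500
        y = rng.normal(size=n)
        fit = KinshipMixedLM(y, None, np.eye(n)).fit()
        G = rng.binomial(2, 0.3, size=(n, 1000)).astype(float)
        res = fit.test_variants(G)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_skipped(self, rng):
        n = 100
        fit = KinshipMixedLM(rng.normal(size=n), None, np.eye(n)).fit()
        res = fit.test_variant(np.zeros(n))
        assert res.skipped and res.reason == "monomorphic"

    def test_non_psd_kinship_reports_eigenvalue(self, rng):
        n = 40
        K = np.eye(n)
        K[0, 1] = K[1, 0] = 2.0  # indefinite
        with pytest.raises(KinshipError, match="eigenvalue"):
            KinshipMixedLM(rng.normal(size=n), None, K).fit()

    def test_from_dataframe_and_summary(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=50), "age": rng.uniform(20, 80, 50)})
        fit = KinshipMixedLM.from_dataframe(df, "y", ["age"]).fit()
        text = fit.summary()
        assert "Kinship mixed model" in text and "sigma_g^2" in text

    def test_vectorized_matches_single_variant(self, rng):
        n = 200
        K = _pedigree_kinship(n, "sibpairs")
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        fit = KinshipMixedLM(y, None, K).fit()
        batch = fit.test_variants(G)
        for j in range(5):
            single = fit.test_variant(G[:, j])
            assert batch.loc[j, "beta"] == pytest.approx(single.beta, rel=1e-9)
            assert batch.loc[j, "se"] == pytest.approx(single.se, rel=1e-9)


class TestSignificanceWeights:
    def test_study_thresholds(self):
        w = SignificanceWeights()
        assert w.threshold("lof") == 2.5e-7
        assert w.threshold("moderate") == 5.0e-8
        assert w.threshold("low") == 4.5e-9
        assert w.threshold("other", dhs=True) == 2.3e-9
        assert w.threshold("other") == 7.5e-10

    def test_lof_vs_remaining_at_1e7(self):
        assert is_significant(1e-7, "lof")
        assert not is_significant(1e-7, "other")

    def test_p_zero_always_significant(self):
        for impact in ("lof", "moderate", "low", "other"):
            assert is_significant(0.0, impact)

    def test_unknown_class_errors(self):
        with pytest.raises(KeyError):
            is_significant(0.01, "mystery")

    def test_disordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SignificanceWeights(lof=1e-9, moderate=5e-8)


class TestEffectConversion:
    def test_homozygote_doubles(self):
        per_allele, homozygote = effect_in_hz(0.11, 19.0909)
        assert per_allele == pytest.approx(2.1, abs=0.01)
        assert homozygote == pytest.approx(2 * per_allele)

    def test_zero_beta(self):
        assert effect_in_hz(0.0, 19.0) == (0.0, 0.0)

    def test_nonpositive_sd_errors(self):
        with pytest.raises(ValueError):
            effect_in_hz(0.1, 0.0)


class TestLD:
    def test_identical_variants(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_independent_variants_small(self, rng):
        g1 = rng.binomial(2, 0.4, 10000).astype(float)
        g2 = rng.binomial(2, 0.4, 10000).astype(float)
        assert ld_r2(g1, g2) < 0.01

    def test_symmetry_and_monomorphic(self, rng):
        g1 = rng.binomial(2, 0.4, 200).astype(float)
        g2 = rng.binomial(2, 0.2, 200).astype(float)
        assert ld_r2(g1, g2) == pytest.approx(ld_r2(g2, g1))
        assert np.isnan(ld_r2(g1, np.zeros(200)))


def _toy_region(rng, m=10):
    beta = rng.normal(0, 0.2, m)
    se = rng.uniform(0.02, 0.1, m)
    return pd.DataFrame({"variant": [f"v{i}" for i in range(m)],
                         "beta": beta, "se": se})


def _credible_oracle(region, W=0.04, target=0.95):
    """Independent oracle: exact ABFs via mpmath-free direct formula,
    minimal subset by exhaustive search over subset sizes."""
    from itertools import combinations
    V = region["se"].to_numpy() ** 2
    z = region["beta"].to_numpy() / region["se"].to_numpy()
    abf = np.sqrt(V / (V + W)) * np.exp(z ** 2 * W / (2 * (V + W)))
    post = abf / abf.sum()
    m = len(post)
    for k in range(1, m + 1):
        best = max(combinations(range(m), k), key=lambda s: post[list(s)].sum())
        if post[list(best)].sum() >= target:
            return set(region["variant"].iloc[list(best)])
    return set(region["variant"])


class TestCredibleSet:
    def test_single_variant_region(self):
        region = pd.DataFrame({"variant": ["v"], "beta": [0.1], "se": [0.02]})
        cs = credible_set(region)
        assert cs.variants == ["v"]
        assert cs.members["posterior"].iloc[0] == pytest.approx(1.0)

    def test_posteriors_sum_to_one(self, rng):
        region = _toy_region(rng)
        abf = wakefield_abf(region["beta"], region["se"])
        assert (abf / abf.sum()).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        region = _toy_region(rng)
        cs = credible_set(region)
        assert set(cs.variants) == _credible_oracle(region)

    def test_mass_target_monotonicity(self, rng):
        for _ in range(10):
            region = _toy_region(rng)
            s95 = credible_set(region, target=0.95)
            s99 = credible_set(region, target=0.99)
            assert set(s95.variants) <= set(s99.variants)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            credible_set(pd.DataFrame(columns=["variant", "beta", "se"]))


class TestColoc:
    def test_r2_threshold(self):
        external = pd.DataFrame({"variant": ["a", "b"], "beta": [-0.64, 0.2],
                                 "p": [3.4e-16, 0.01]})
        r2 = {"lead": 1.0, "a": 1.0, "b": 0.5}
        out = coloc_overlap("lead", external, r2)
        assert out["variant"].tolist() == ["a"]
        assert out["beta"].iloc[0] == -0.64  # effect sign reported

    def test_lead_absent_errors(self):
        with pytest.raises(KeyError):
            coloc_overlap("lead", pd.DataFrame({"variant": []}), {})


class TestManhattanPlot:
    def test_returns_axes_with_threshold_lines(self, tmp_path, rng):
        import matplotlib
        matplotlib.use("Agg")
        from vocalgwas.assoc import plot_manhattan
        df = pd.DataFrame({"variant": [f"v{i}" for i in range(50)],
                           "p": rng.uniform(1e-12, 1, 50),
                           "skipped": [False] * 50})
        ax = plot_manhattan(df)
        assert len(ax.lines) == 2  # strictest + most lenient thresholds
        assert ax.get_ylabel().startswith("$-")
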