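"""Association mapping: OLS correctness, filters, inflation,
heritability."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rhizonet import gwas as gw
from rhizonet.errors import ConfigError
from rhizonet.io import GenotypeMatrix


def _geno(arr, hosts=None, snps=None):
    arr = np.asarray(arr, dtype=float)
    hosts = hosts or [f"h{i}" for i in range(arr.shape[0])]
    snps = snps or [f"s{j}" for j in range(arr.shape[1])]
    return GenotypeMatrix(calls=pd.DataFrame(arr, index=hosts, columns=snps))


class TestMafFilter:
    @pytest.mark.parametrize(
        "freq,kept",
        [(0.04, False), (0.5, True), (0.05, False), (0.051, True), (0.96, False)],
    )
    def test_strict_threshold(self, freq, kept):
        n = 1000
        col = np.zeros(n)
        col[: int(round(freq * n))] = 1.0
        geno = _geno(col[:, None])
        out = gw.maf_filter(geno, min_maf=0.05)
        assert (out.calls.shape[1] == 1) is kept

    def test_all_missing_dropped_with_warning(self):
        arr = np.array([[np.nan, 1.0], [np.nan, 0.0], [np.nan, 1.0], [np.nan, 0.0]])
        with pytest.warns(UserWarning):
            out = gw.maf_filter(_geno(arr), min_maf=0.05)
        assert out.calls.shape[1] == 1

    def test_maf_on_nonmissing_calls(self):
        arr = np.array([[1.0], [1.0], [0.0], [np.nan]])
        maf = gw.minor_allele_frequency(_geno(arr).calls)
        assert maf.iloc[0] == pytest.approx(1 / 3)


class TestPrepareGenotypes:
    def test_high_missingness_dropped(self):
        arr = np.array(
            [[0.0, 0.0], [1.0, np.nan], [0.0, np.nan], [1.0, np.nan], [0.0, 1.0],
             [1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
        )
        with pytest.warns(UserWarning):
            design = gw.prepare_genotypes(_geno(arr), max_missing=0.10)
        assert design.shape[1] == 1

    def test_mean_imputation(self):
        arr = np.array([[0.0], [1.0], [np.nan], [1.0]])
        design = gw.prepare_genotypes(_geno(arr), max_missing=0.5)
        assert design.iloc[2, 0] == pytest.approx(2 / 3)


class TestAssociate:
    def test_closed_form_four_points(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = gw.associate(y, pd.DataFrame({"s": [0.0, 0.0, 1.0, 1.0]}))
        assert res.loc["s", "beta"] == pytest.approx(2.0)

    def test_constant_phenotype_degenerate(self):
        y = np.full(6, 3.3)
        res = gw.associate(y, pd.DataFrame({"s": [0, 1, 0, 1, 0, 1.0]}))
        assert res.loc["s", "beta"] == 0.0 and res.loc["s", "p_value"] == 1.0

    def test_perfect_fit(self):
        x = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1.0])
        res = gw.associate(x.copy(), pd.DataFrame({"s": x}))
        assert res.loc["s", "p_value"] < 1e-10
        assert res.loc["s", "r2"] == pytest.approx(1.0)

    def test_monomorphic_snp_skipped(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = gw.associate(y, pd.DataFrame({"mono": [1.0] * 4, "ok": [0, 1, 0, 1.0]}))
        assert res.attrs["skipped_snps"] == ["mono"]
        assert res.loc["mono", "p_value"] == 1.0

    def test_matches_statsmodels(self, rng):
        """Closed-form beta/se/p equal the textbook OLS fit on random
        small datasets."""
        for _ in range(100):
            n = int(rng.integers(8, 30))
            x = rng.binomial(1, rng.uniform(0.2, 0.8), size=n).astype(float)
            if x.std() == 0:
                continue
            y = rng.normal(size=n) + rng.normal() * x
            res = gw.associate(y, pd.DataFrame({"s": x}))
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert res.loc["s", "beta"] == pytest.approx(fit.params[1], rel=1e-10)
            assert res.loc["s", "se"] == pytest.approx(fit.bse[1], rel=1e-10)
            assert res.loc["s", "p_value"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_covariates_match_statsmodels(self, rng):
        n = 50
        x = rng.binomial(1, 0.4, size=n).astype(float)
        c = rng.normal(size=(n, 2))
        y = 0.5 * x + c @ np.array([1.0, -2.0]) + rng.normal(size=n)
        res = gw.associate(y, pd.DataFrame({"s": x}), covariates=c)
        X = sm.add_constant(np.column_stack([c, x]))
        fit = sm.OLS(y, X).fit()
        assert res.loc["s", "beta"] == pytest.approx(fit.params[-1], rel=1e-8)
        assert res.loc["s", "p_value"] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_too_few_hosts(self):
        with pytest.raises(ConfigError):
            gw.associate(np.array([1.0, 2.0]), pd.DataFrame({"s": [0, 1.0]}))

    def test_covariates_reduce_inflation_under_structure(self):
        """Q-model covariates deflate lambda_GC when phenotype and
        allele frequencies share subpopulation structure."""
        from rhizonet.simulate import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(
            n_hosts=300, n_snps=1000, n_subpops=3, divergence=0.2,
            maf_range=(0.1, 0.5), seed=13,
        )
        geno = simulate_genotypes(cfg)
        subpop = np.arange(cfg.n_hosts) % 3
        rng = np.random.default_rng(5)
        y = subpop * 1.0 + rng.normal(size=cfg.n_hosts)
        design = gw.prepare_genotypes(geno)
        lam_raw, _ = gw.qq_inflation(gw.associate(y, design)["p_value"])
        Q = np.column_stack([(subpop == k).astype(float) for k in (1, 2)])
        lam_adj, _ = gw.qq_inflation(gw.associate(y, design, covariates=Q)["p_value"])
        assert lam_adj < lam_raw
        assert lam_raw > 1.2 and 0.8 < lam_adj < 1.2


class TestSignificantHits:
    def _res(self, ps):
        return pd.DataFrame(
            {"p_value": ps, "beta": 0.0, "se": 1.0, "maf": 0.2, "n_used": 10, "r2": 0.0},
            index=pd.Index([f"s{i}" for i in range(len(ps))], name="snp_id"),
        )

    def test_inclusive_boundary(self):
        hits = gw.significant_hits(self._res([1e-5, 1.1e-5, 0.5]), 5.0)
        assert list(hits.index) == ["s0"]

    def test_sorted_by_p(self):
        hits = gw.significant_hits(self._res([1e-7, 1e-9, 1e-6]), 5.0)
        assert list(hits.index) == ["s1", "s0", "s2"]

    def test_null_yields_no_hits(self, rng):
        ps = rng.uniform(1e-4, 1, size=2000)
        assert len(gw.significant_hits(self._res(ps), 5.0)) == 0


class TestQqInflation:
    def test_uniform_p_lambda_near_one(self, rng):
        lam, coords = gw.qq_inflation(rng.uniform(size=100_000))
        assert 0.97 <= lam <= 1.03
        assert len(coords) == 100_000

    def test_halved_p_inflates(self, rng):
        p = rng.uniform(size=20_000)
        lam_half, _ = gw.qq_inflation(p / 2)
        assert lam_half > 1.0

    def test_order_invariant(self, rng):
        p = rng.uniform(size=5000)
        assert gw.qq_inflation(p)[0] == gw.qq_inflation(p[::-1])[0]


class TestHeritability:
    def test_no_hits_zero(self, rng):
        h = gw.snp_heritability(
            rng.normal(size=20), pd.DataFrame(), pd.DataFrame({"s": rng.binomial(1, 0.5, 20)})
        )
        assert h.total == 0.0

    def test_noiseless_single_snp_full_h2(self):
        x = np.array([0, 1, 0, 1, 1, 0, 0, 1.0])
        hits = pd.DataFrame(index=pd.Index(["s"], name="snp_id"))
        h = gw.snp_heritability(2.0 * x, hits, pd.DataFrame({"s": x}))
        assert h.per_snp.loc["s", "h2"] == pytest.approx(1.0)
        assert h.total == pytest.approx(1.0)

    def test_expected_r2_one_quarter(self, rng):
        """y = beta*x + e with signal:noise variance 1:3 gives h2 ~ 0.25."""
        n = 10_000
        x = rng.binomial(1, 0.5, size=n).astype(float)
        beta = np.sqrt(1.0 / x.var())
        y = beta * x + rng.normal(0, np.sqrt(3.0), size=n)
        hits = pd.DataFrame(index=pd.Index(["s"], name="snp_id"))
        h = gw.snp_heritability(y, hits, pd.DataFrame({"s": x}))
        assert 0.22 <= h.per_snp.loc["s", "h2"] <= 0.28

    def test_ridge_fallback_flagged(self, rng):
        n = 10
        X = pd.DataFrame(
            rng.binomial(1, 0.5, size=(n, 12)).astype(float),
            columns=[f"s{j}" for j in range(12)],
        )
        y = rng.normal(size=n)
        hits = pd.DataFrame(index=pd.Index(list(X.columns), name="snp_id"))
        h = gw.snp_heritability(y, hits, X)
        assert h.ridge_fallback and 0.0 <= h.total <= 1.0
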