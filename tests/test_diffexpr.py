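import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonynet import diffexpr
from colonynet.diffexpr import (
    DEAccounting,
    NegativeBinomialWald,
    bh_adjust,
    de_accounting,
    estimate_dispersions,
    filter_low_count_genes,
    nb_wald_test,
    size_factors,
)


def nb_counts(rng, q, mu_scale=None, dispersion=0.3, n=60):
    """NB gene x worker counts with per-gene base means q."""
    mu = q[:, None] * (mu_scale if mu_scale is not None else np.ones((1, n)))
    r = 1.0 / dispersion
    Y = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(
        Y, index=[f"g{i}" for i in range(len(q))], columns=[f"w{i}" for i in range(mu.shape[1])]
    )


class TestFilterLowCountGenes:
    def test_boundary_kept(self):
        counts = pd.DataFrame(
            [[99], [100], [101]], index=list("abc"), columns=["w"]
        )
        kept = filter_low_count_genes(counts)
        assert list(kept.index) == ["b", "c"]

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            filter_low_count_genes(pd.DataFrame(np.zeros((3, 4))))


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_ratio_two(self):
        base = np.array([10, 20, 40, 80, 160])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        counts = nb_counts(rng, np.exp(rng.normal(4, 1, 50)), n=8)
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_step_up(self, ps):
        """BH equals the direct p*m/rank + reverse-cummin formula."""
        p = np.asarray(ps)
        out = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        assert np.allclose(out, expected)
        assert (out >= p - 1e-12).all()


class TestDispersions:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(1)
        q = np.exp(rng.normal(4, 1, 400))
        Y = rng.poisson(q[:, None] * np.ones((1, 100)))
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(400)],
                              columns=[f"w{i}" for i in range(100)])
        disp = estimate_dispersions(counts)
        assert np.median(disp) <= 0.01

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        q = np.exp(rng.normal(4, 1, 400))
        counts = nb_counts(rng, q, dispersion=0.5, n=200)
        disp = estimate_dispersions(counts)
        assert 0.3 <= np.median(disp) <= 0.7

    def test_constant_counts_floored(self):
        counts = pd.DataFrame(np.full((5, 10), 7))
        disp = estimate_dispersions(counts)
        assert (disp <= 1e-6).all()

    def test_needs_four_workers(self):
        with pytest.raises(ValueError):
            estimate_dispersions(pd.DataFrame(np.ones((5, 3))))


class TestNBWald:
    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(0)
        counts = nb_counts(rng, np.full(10, 100.0), n=20)
        cov = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="constant"):
            nb_wald_test(counts, cov)

    def test_matches_statsmodels_glm_per_gene(self):
        """Coefficients and standard errors agree with an independent
        per-gene NB GLM fit (statsmodels, fixed dispersion, same offset)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        G, n = 6, 80
        q = np.full(G, 200.0)
        m = rng.beta(0.5, 0.5, n)
        mu = q[:, None] * np.exp2(1.0 * m[None, :])
        Y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))  # dispersion 0.5
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                              columns=[f"w{i}" for i in range(n)])
        cov = pd.Series(m, index=counts.columns)
        disp = pd.Series(0.5, index=counts.index)
        unit_sf = pd.Series(1.0, index=counts.columns)
        ours = nb_wald_test(counts, cov, size_factors_=unit_sf, dispersions=disp)
        X = sm.add_constant(m)
        ln2 = np.log(2.0)
        for g in counts.index:
            fit = sm.GLM(
                counts.loc[g].to_numpy(), X,
                family=sm.families.NegativeBinomial(alpha=0.5),
            ).fit()
            assert ours.loc[g, "log2FoldChange"] == pytest.approx(
                fit.params[1] / ln2, rel=1e-3, abs=1e-4
            )
            assert ours.loc[g, "lfcSE"] == pytest.approx(
                fit.bse[1] / ln2, rel=5e-3
            )

    def test_agrees_with_pydeseq2_on_shared_fixture(self):
        """Independent cross-check against a full DE framework: effect
        estimates strongly correlated and DE calls largely shared, despite
        different dispersion machinery."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(4)
        G, n = 150, 60
        q = np.exp(rng.normal(np.log(50), 1.0, G))
        m = rng.beta(0.5, 0.5, n)
        beta = np.zeros(G)
        beta[:20] = 1.0
        mu = q[:, None] * np.exp2(beta[:, None] * m[None, :])
        r = 1 / 0.3
        Y = rng.negative_binomial(r, r / (r + mu))
        genes = [f"g{i}" for i in range(G)]
        samples = [f"s{i}" for i in range(n)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=pd.DataFrame(Y.T, index=samples, columns=genes),
                metadata=pd.DataFrame({"maturity": m}, index=samples),
                design="~maturity",
                quiet=True,
            )
            dds.deseq2()
            stats = DeseqStats(dds, contrast=np.array([0.0, 1.0]), quiet=True)
            stats.summary()
        ref = stats.results_df
        ours = nb_wald_test(
            pd.DataFrame(Y, index=genes, columns=samples),
            pd.Series(m, index=samples),
        )
        r_lfc = np.corrcoef(ref["log2FoldChange"], ours["log2FoldChange"])[0, 1]
        assert r_lfc > 0.95
        a = set(ref.index[ref["padj"] < 0.05])
        b = set(ours.index[ours["significant"]])
        jaccard = len(a & b) / max(1, len(a | b))
        assert jaccard > 0.6

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        G, n = 300, 150
        q = np.exp(rng.normal(np.log(80), 0.8, G))
        m = rng.beta(0.5, 0.5, n)
        beta = np.zeros(G)
        beta[:30] = 1.0
        beta[30:60] = -1.0
        mu = q[:, None] * np.exp2(beta[:, None] * m[None, :])
        Y = rng.negative_binomial(1 / 0.3, (1 / 0.3) / (1 / 0.3 + mu))
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                              columns=[f"w{i}" for i in range(n)])
        res = nb_wald_test(counts, pd.Series(m, index=counts.columns))
        est_up = res.iloc[:30]["log2FoldChange"].median()
        est_dn = res.iloc[30:60]["log2FoldChange"].median()
        assert est_up == pytest.approx(1.0, abs=0.2)
        assert est_dn == pytest.approx(-1.0, abs=0.2)

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(6)
        q = np.exp(rng.normal(np.log(100), 0.5, 50))
        counts = nb_counts(rng, q, n=40)
        cov = pd.Series(rng.random(40), index=counts.columns)
        est = NegativeBinomialWald(alpha=0.05).fit(counts, covariate=cov)
        assert est.results_.shape[0] <= 50
        assert (est.results_["padj"] >= est.results_["pvalue"] - 1e-12).all()
        assert set(est.de_genes_) == set(
            est.results_.index[est.results_["significant"]]
        )


@pytest.fixture(scope="module")
def accounting():
    from colonynet.config import ColonyConfig
    from colonynet.synthetic import generate_expression, generate_workers

    rng = np.random.default_rng(0)
    cfg = ColonyConfig(
        n_colonies=2, n_workers_per_colony=60, n_genes=300, n_de_genes=40,
        de_effect_size=1.5, seed=0,
    )
    workers = generate_workers(cfg, rng)
    expr, _ = generate_expression(workers, cfg, rng)
    idx = workers.set_index("worker_id")
    m = idx["maturity"]
    variables = pd.DataFrame(
        {
            "social": m,
            "behavior": np.clip(m + 0.3 * rng.standard_normal(len(m)), 0, 1),
            "age": idx["age_weeks"].astype(float),
            "physical": m + 0.5 * rng.standard_normal(len(m)),
            "microbiota": rng.standard_normal(len(m)),
        }
    )
    counts = filter_low_count_genes(expr)
    return de_accounting(counts, variables, idx["colony_id"])


class TestDEAccounting:
    def test_shape_five_rows_six_columns(self, accounting):
        assert accounting.table.shape == (5, 6)
        assert list(accounting.table.columns[:1]) == ["n_de"]

    def test_diagonal_undefined(self, accounting):
        for v in accounting.table.index:
            assert np.isnan(accounting.table.loc[v, v])

    def test_percentages_bounded(self, accounting):
        vals = accounting.table.drop(columns="n_de").to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 100)).all()

    def test_causal_asymmetry(self, accounting):
        """Expression is driven by latent maturity only, so maturity-DE genes
        survive controlling for the noisy behaviour proxy better than the
        converse."""
        t = accounting.table
        assert t.loc["social", "behavior"] > t.loc["behavior", "social"]

    def test_self_control_guard(self):
        """A control collinear with the variable yields an empty controlled
        set rather than a singular fit."""
        rng = np.random.default_rng(1)
        q = np.exp(rng.normal(np.log(120), 0.5, 60))
        counts = nb_counts(rng, q, n=50)
        x = pd.Series(rng.random(50), index=counts.columns)
        variables = pd.DataFrame({"a": x, "b": 2 * x + 1})
        colony = pd.Series("c1", index=counts.columns)
        acc = de_accounting(counts, variables, colony)
        assert acc.table.loc["a", "b"] == 0.0 or np.isnan(acc.table.loc["a", "b"])

    def test_returns_dataclass_with_companion_tables(self, accounting):
        assert isinstance(accounting, DEAccounting)
        assert accounting.fraction_of_genes.shape[0] == 5
        assert accounting.n_genes_tested > 0
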