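"""Correlation filter, Pearson p-values, covariate-adjusted DE, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flowsig.aorta import (
    bh_select,
    corr_filter,
    de_covariate,
    negative_control,
    pearson_pvalue,
    signed_fold_change,
)
from flowsig.datatypes import PhenotypeTable, QuerySet
from flowsig.io import load_table1
from flowsig.simulate import AortaConfig, gen_aorta

from conftest import make_dataset


class TestCorrFilter:
    def test_candidate_identical_to_query_passes(self):
        ds = make_dataset([[1, 2, 3, 4], [1, 2, 3, 4]], ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]))
        assert recs[0].max_abs_r == pytest.approx(1.0)
        assert recs[0].passed_corr

    def test_weak_true_correlation_rejected_at_cutoff(self):
        # candidate = query + noise, theoretical R = 0.2 at n = 500
        rng = np.random.default_rng(5)
        n = 500
        q = rng.normal(size=n)
        r_target = 0.2
        c = r_target * q + np.sqrt(1 - r_target**2) * rng.normal(size=n)
        ds = make_dataset(np.vstack([q, c]), ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]))
        assert recs[0].max_abs_r == pytest.approx(0.2, abs=0.09)
        assert not recs[0].passed_corr

    def test_hand_computed_negative_correlation(self):
        # corr([0,1,1,2], [1,1,2,0]) = -0.5 by hand; |R| mode passes nothing
        # at 0.40 cutoff... 0.5 > 0.40, so it passes via the magnitude.
        ds = make_dataset([[0, 1, 1, 2], [1, 1, 2, 0]], ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]))
        assert recs[0].max_abs_r == pytest.approx(0.5, abs=1e-12)
        assert recs[0].passed_corr

    def test_signed_mode_rejects_anticorrelated(self):
        ds = make_dataset([[0, 1, 1, 2], [1, 1, 2, 0]], ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]), use_abs=False)
        assert not recs[0].passed_corr

    def test_constant_candidate_excluded(self):
        ds = make_dataset([[1, 2, 3, 4], [5, 5, 5, 5]], ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]))
        assert recs == []

    def test_strict_inequality_at_cutoff(self):
        ds = make_dataset([[0, 1, 1, 2], [1, 1, 2, 0]], ["Q1", "C1"])
        recs = corr_filter(ds, ["C1"], QuerySet("q", ["Q1", "Q2"]), r_cutoff=0.5)
        assert not recs[0].passed_corr  # 0.5 is not > 0.5


class TestPearsonPvalue:
    def test_zero_correlation_gives_one(self):
        for n in (3, 10, 127):
            assert pearson_pvalue(0.0, n) == 1.0

    def test_matches_permutation_oracle(self):
        # permutation distribution of |r| under exchangeability, n=30
        rng = np.random.default_rng(77)
        n, r_obs = 30, 0.5
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        r_obs = np.corrcoef(x, y)[0, 1]
        n_perm = 100_000
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        perms = np.array([np.mean(xc * yc[rng.permutation(n)]) for _ in range(n_perm)])
        p_perm = (np.abs(perms) >= abs(r_obs)).mean()
        p_t = pearson_pvalue(r_obs, n)
        mc_err = 3 * np.sqrt(max(p_t, 1e-6) * (1 - p_t) / n_perm)
        assert p_perm == pytest.approx(p_t, abs=max(mc_err, 2e-3))

    def test_strictly_decreasing_in_magnitude(self):
        ps = [pearson_pvalue(r, 20) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)


class TestDeCovariate:
    def test_zero_beta_gives_unit_fold_change(self, simple_phenotypes):
        # constant gene: beta exactly 0 -> fc +1.0
        ds = make_dataset([[5.0, 5.0, 5.0, 5.0]], ["G1"], samples=["S0", "S1", "S2", "S3"])
        de = de_covariate(ds, simple_phenotypes)
        assert de.loc["G1", "fc_signed"] == pytest.approx(1.0)

    def test_fold_change_direction_convention(self):
        # adjusted BAV level 2^-0.713 of TAV -> fc ~ -1.64 (lower in BAV)
        assert signed_fold_change(-0.713) == pytest.approx(-1.64, abs=0.005)
        assert signed_fold_change(0.713) == pytest.approx(1.64, abs=0.005)
        # |fc| = 2^|beta|, sign-consistent
        for b in (-2.0, -0.3, 0.0, 0.4, 1.5):
            fc = signed_fold_change(b)
            assert abs(fc) == pytest.approx(2 ** abs(b))
            assert np.sign(fc) == (1.0 if b >= 0 else -1.0)

    def test_matches_statsmodels_ols_oracle(self):
        cfg = AortaConfig(
            n_bav=12, n_tav=8, gene_universe=[f"G{i}" for i in range(20)],
            affected_genes=["G0", "G1"], effect_size=-0.6, module_genes=[], seed=3,
        )
        ds, pheno, _ = gen_aorta(cfg)
        de = de_covariate(ds, pheno)
        t = pheno.table
        X = sm.add_constant(
            np.column_stack(
                [
                    (t["cuspidity"] == "BAV").astype(float),
                    t["dilation"], t["stenosis"], t["regurgitation"],
                ]
            ).astype(float)
        )
        for g in ds.genes:
            fit = sm.OLS(ds.values.loc[g].to_numpy(), X).fit()
            assert de.loc[g, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert de.loc[g, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert de.loc[g, "p_cusp"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_casewise_missing_matches_statsmodels(self, simple_phenotypes):
        vals = np.array([[1.0, np.nan, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        ds = make_dataset(vals, ["G1", "G2"], samples=["S0", "S1", "S2", "S3"])
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(4)],
                    "cuspidity": ["BAV", "BAV", "TAV", "TAV"],
                    "dilation": [0, 0, 0, 0],
                    "stenosis": [0, 0, 0, 0],
                    "regurgitation": [0, 0, 0, 0],
                }
            )
        )
        de = de_covariate(ds, pheno)
        # G1 drops S1 casewise; with 3 points and 2 params, df=1
        assert de.loc["G1", "n_used"] == 3
        assert de.loc["G2", "n_used"] == 4

    def test_all_zero_covariates_equals_pooled_t_test(self):
        rng = np.random.default_rng(12)
        n1, n2 = 9, 7
        y = rng.normal(size=n1 + n2)
        ds = make_dataset(y[None, :], ["G1"], samples=[f"S{i}" for i in range(n1 + n2)])
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(n1 + n2)],
                    "cuspidity": ["BAV"] * n1 + ["TAV"] * n2,
                    "dilation": 0, "stenosis": 0, "regurgitation": 0,
                }
            )
        )
        de = de_covariate(ds, pheno)
        t_stat, p = stats.ttest_ind(y[:n1], y[n1:], equal_var=True)
        assert de.loc["G1", "p_cusp"] == pytest.approx(p, abs=1e-10)
        assert de.loc["G1", "beta"] == pytest.approx(y[:n1].mean() - y[n1:].mean(), abs=1e-10)

    def test_collinear_design_yields_error_records_not_crash(self):
        ds = make_dataset([[1.0, 2.0, 3.0, 4.0]], ["G1"], samples=[f"S{i}" for i in range(4)])
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(4)],
                    "cuspidity": ["BAV", "BAV", "TAV", "TAV"],
                    "dilation": [1, 1, 0, 0],  # identical to cuspidity
                    "stenosis": 0, "regurgitation": 0,
                }
            )
        )
        de = de_covariate(ds, pheno)
        assert de.loc["G1", "error"] is not None
        assert np.isnan(de.loc["G1", "p_cusp"])


def brute_force_bh(pvals, q):
    """Independent step-up: sort ascending, largest k with p_(k) <= k q/m."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_star = rank
    return {order[i] for i in range(k_star)}


class TestBHSelect:
    def test_all_ones_nothing_rejected(self):
        rejected, thr = bh_select(np.ones(10))
        assert rejected == set() and thr == 0.0

    def test_hand_worked_example_all_rejected(self):
        p = pd.Series([0.001, 0.01, 0.02, 0.04, 0.05], index=list("ABCDE"))
        rejected, thr = bh_select(p, q=0.05)
        assert rejected == set("ABCDE")  # p_(5)=0.05 <= 5*0.05/5
        assert thr == 0.05

    def test_table1_genes_all_below_realized_threshold(self):
        df = load_table1(as_frame=True)
        assert (df["asap_p"] < 0.0140).all()
        assert len(df) == 44

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
        ),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_brute_force_and_order_invariant(self, pvals, q):
        rejected, thr = bh_select(np.array(pvals), q=q)
        assert rejected == brute_force_bh(pvals, q)
        # order invariance: reversed input selects the same p-values
        rej_rev, _ = bh_select(np.array(pvals[::-1]), q=q)
        assert sorted(pvals[len(pvals) - 1 - i] for i in rej_rev) == sorted(
            pvals[i] for i in rejected
        )

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_q(self, pvals):
        r1, _ = bh_select(np.array(pvals), q=0.02)
        r2, _ = bh_select(np.array(pvals), q=0.10)
        assert r1 <= r2


class TestNegativeControl:
    @staticmethod
    def _null_world(seed):
        genes, module = [], []
        queries = ["Q0", "Q1", "Q2", "Q3", "Q4"]
        correlated = [f"C{i}" for i in range(72)]
        genes = queries + correlated + [f"N{i}" for i in range(23)]
        cfg = AortaConfig(
            n_bav=40, n_tav=30, gene_universe=genes, affected_genes=[],
            effect_size=0.0, module_genes=queries + correlated,
            module_loading=0.6, seed=seed,
        )
        ds, pheno, _ = gen_aorta(cfg)
        return ds, pheno, correlated, QuerySet("q", queries)

    def test_positive_control_returns_nonempty(self):
        genes = [f"G{i}" for i in range(30)]
        queries = ["Q0", "Q1"]
        cfg = AortaConfig(
            n_bav=40, n_tav=30, gene_universe=queries + genes,
            affected_genes=genes[:8], effect_size=-1.0,
            module_genes=queries + genes[:20], module_loading=0.6,
            noise_sd=0.3, seed=2,
        )
        ds, pheno, _ = gen_aorta(cfg)
        report = negative_control(ds, pheno, genes[:20], QuerySet("q", queries))
        assert report.n_fdr_rejected > 0

    def test_empty_screened_list_is_degenerate_but_clean(self, simple_phenotypes):
        ds = make_dataset([[1, 2, 3, 4]], ["Q1"], samples=["S0", "S1", "S2", "S3"])
        report = negative_control(ds, simple_phenotypes, [], QuerySet("q", ["Q1", "Q2"]))
        assert report.is_clean and report.n_screened == 0

    def test_null_world_mostly_clean(self):
        # fast spot-check (the 100-replicate version is an acceptance test)
        clean = 0
        for seed in range(10):
            ds, pheno, screened, queries = self._null_world(seed)
            clean += negative_control(ds, pheno, screened, queries).is_clean
        assert clean >= 8
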