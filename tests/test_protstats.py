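"""LFQ preprocessing, downshifted-normal imputation, moderated t and BH."""

import itertools
import subprocess

import numpy as np
import pytest
from scipy import stats

from d2bscreen.protstats import (
    IntensityMatrix,
    PipelineError,
    PipelineParams,
    bh_adjust,
    estimate_variance_prior,
    finalize,
    impute,
    moderated_t,
    preprocess,
    run_pipeline,
    volcano_table,
)
from d2bscreen.synth import SimConfig, gen_proteomics


def _matrix(values, groups=None, proteins=None, log_scale=False):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return IntensityMatrix(
        proteins=proteins or [f"P{i}" for i in range(n)],
        samples=[f"s{j}" for j in range(m)],
        groups=groups or ["control"] * (m // 2) + ["treated"] * (m - m // 2),
        values=values,
        log_scale=log_scale,
    )


class TestPreprocess:
    def test_valid_value_filter_strictly_greater(self):
        """3/4 = 0.75 > 0.70 kept; 2/4 = 0.5 dropped."""
        nan = np.nan
        m = _matrix(
            [
                [8.0, 8.0, 8.0, nan],  # 75% -> kept
                [8.0, 8.0, nan, nan],  # 50% -> dropped
                [8.0, 8.0, 8.0, 8.0],  # 100% -> kept
            ]
        )
        out = preprocess(m, PipelineParams())
        assert out.proteins == ["P0", "P2"]

    def test_median_normalization_centers_each_sample(self):
        rng = np.random.default_rng(0)
        m = _matrix(np.exp(rng.normal(10, 1, size=(51, 4))))
        out = preprocess(m, PipelineParams())
        med = np.nanmedian(out.values, axis=0)
        assert np.allclose(med, 0.0, atol=1e-12)

    def test_contaminant_blocklist(self):
        m = _matrix(np.full((3, 4), 100.0))
        out = preprocess(m, PipelineParams(contaminants=frozenset({"P1"})))
        assert out.proteins == ["P0", "P2"]

    def test_log2_applied_once(self):
        m = _matrix(np.full((3, 4), 1024.0))
        out = preprocess(m, PipelineParams())
        # 2^10 -> 10, then median-centered to 0
        assert np.allclose(out.values, 0.0)
        assert out.log_scale

    def test_everything_filtered_raises(self):
        m = _matrix([[np.nan, 1.0, np.nan, 1.0]])
        with pytest.raises(PipelineError):
            preprocess(m, PipelineParams())


class TestImpute:
    def test_downshifted_distribution_monte_carlo(self):
        """Sample mean 20, SD 2 -> imputed draws from Normal(16.4, 0.6^2)."""
        rng = np.random.default_rng(5)
        n = 20000
        observed = rng.normal(20.0, 2.0, size=n)
        col = np.concatenate([observed, np.full(10000, np.nan)])
        m = _matrix(col[:, None], groups=["control"], log_scale=True)
        out = impute(m, PipelineParams(seed=1))
        imputed = out.values[n:, 0]
        mu_expected = observed.mean() - 1.8 * observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu_expected, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * observed.std(ddof=1), rel=0.05)

    def test_no_missing_is_identity(self):
        m = _matrix(np.ones((5, 4)), log_scale=True)
        out = impute(m, PipelineParams(seed=0))
        assert np.array_equal(out.values, m.values)

    def test_seeded_reproducibility(self):
        vals = np.full((10, 4), 20.0)
        vals += np.arange(10)[:, None]  # give each sample a spread
        vals[::3, 1] = np.nan
        a = impute(_matrix(vals.copy(), log_scale=True), PipelineParams(seed=7))
        b = impute(_matrix(vals.copy(), log_scale=True), PipelineParams(seed=7))
        c = impute(_matrix(vals.copy(), log_scale=True), PipelineParams(seed=8))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_too_few_observed_raises(self):
        vals = np.array([[np.nan], [np.nan], [1.0]])
        with pytest.raises(PipelineError):
            impute(_matrix(vals, groups=["control"], log_scale=True), PipelineParams())


class TestModeratedT:
    def test_equal_group_means_give_null_result(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(50, 8))
        vals[0, :4] = [1.0, 2.0, 3.0, 4.0]
        vals[0, 4:] = [4.0, 3.0, 2.0, 1.0]  # same mean both groups
        m = _matrix(vals, log_scale=True)
        res = moderated_t(m)
        assert res[0].log2fc == pytest.approx(0.0)
        assert res[0].t_mod == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_infinite_prior_limit_equals_pooled_common_variance_t(self):
        """All gene variances equal -> complete shrinkage to the common
        pooled variance; the statistic equals ordinary t with that variance."""
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=4)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, var 1
        vals = np.stack([np.concatenate([base * 0.5, base * 0.5 + d]) for d in np.linspace(0, 2, 30)])
        m = _matrix(vals, log_scale=True)
        res = moderated_t(m)
        assert np.isinf(res[0].d0)
        s2_common = np.mean([r.s2_g for r in res])
        for r in res:
            expected = r.log2fc / np.sqrt(s2_common * (1 / 4 + 1 / 4))
            assert r.t_mod == pytest.approx(expected, rel=1e-9)

    def test_zero_prior_df_reduces_to_student_t(self):
        """With d0 = 0 the moderated test is the ordinary pooled t-test."""
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(40, 8))
        m = _matrix(vals, log_scale=True)
        res = moderated_t(m, prior=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(vals[:, 4:], vals[:, :4], axis=1)
        for r, t, p in zip(res, t_ref, p_ref):
            assert r.t_mod == pytest.approx(t, rel=1e-9)
            assert r.p == pytest.approx(p, rel=1e-9)

    def test_type_i_error_on_null_simulation(self):
        """1000 null proteins, 4 vs 4: rejection rate at p < 0.05 is ~5%."""
        sim = gen_proteomics(
            SimConfig(seed=17, n_spiked=0, spike_effect=0.0, missing_max=0.0)
        )
        params = PipelineParams(seed=17)
        m = impute(preprocess(sim.matrix, params), params)
        res = moderated_t(m)
        frac = np.mean([r.p < 0.05 for r in res])
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_group_size_validation(self):
        m = _matrix(np.ones((3, 3)), groups=["control", "control", "treated"])
        with pytest.raises(PipelineError):
            moderated_t(m)

    def test_row_and_column_order_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 1, size=(30, 8))
        m = _matrix(vals, log_scale=True)
        res = {r.protein: (r.t_mod, r.p) for r in moderated_t(m)}
        row_perm = rng.permutation(30)
        col_perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        m2 = IntensityMatrix(
            proteins=[m.proteins[i] for i in row_perm],
            samples=[m.samples[j] for j in col_perm],
            groups=[m.groups[j] for j in col_perm],
            values=vals[np.ix_(row_perm, col_perm)],
            log_scale=True,
        )
        res2 = {r.protein: (r.t_mod, r.p) for r in moderated_t(m2)}
        for prot, (t, p) in res.items():
            assert res2[prot][0] == pytest.approx(t, rel=1e-12)
            assert res2[prot][1] == pytest.approx(p, rel=1e-12)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same matrix."""
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, size=(200, 8))
        vals[:5, 4:] -= 2.0
        m = _matrix(vals, log_scale=True)
        res = moderated_t(m)

        tsv = tmp_path / "mat.tsv"
        np.savetxt(tsv, vals, delimiter="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            design <- cbind(Intercept=1, Treated=rep(c(0,1), each=4))
            fit <- eBayes(lmFit(x, design))
            out <- cbind(fit$t[,2], fit$p.value[,2], fit$df.prior, fit$s2.prior)
            write.table(format(out, digits=12), commandArgs(TRUE)[2],
                        row.names=FALSE, col.names=FALSE, quote=FALSE)
            """
        )
        out_path = tmp_path / "limma_out.txt"
        subprocess.run(
            ["Rscript", str(script), str(tsv), str(out_path)],
            check=True, capture_output=True,
        )
        ref = np.loadtxt(out_path)
        assert res[0].d0 == pytest.approx(ref[0, 2], rel=1e-6)
        assert res[0].s0_2 == pytest.approx(ref[0, 3], rel=1e-6)
        for r, (t_ref, p_ref, _, _) in zip(res, ref):
            assert r.t_mod == pytest.approx(t_ref, rel=1e-8)
            assert r.p == pytest.approx(p_ref, rel=1e-6)


def bh_oracle(p):
    """Brute-force step-up: adjusted p(i) = min over k >= i of m * p(k) / k."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        adj[i] = min(
            min(m * p[order[k - 1]] / k for k in range(rank_i, m + 1)), 1.0
        )
    return adj


class TestBH:
    def test_worked_example(self):
        adj, sig = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert sig.all()

    def test_single_p(self):
        adj, sig = bh_adjust([0.2])
        assert adj[0] == pytest.approx(0.2)
        assert not sig[0]

    def test_all_ones(self):
        adj, sig = bh_adjust([1.0] * 5)
        assert np.allclose(adj, 1.0)
        assert not sig.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(PipelineError):
            bh_adjust([0.5, 1.5])

    def test_exhaustive_oracle_agreement_up_to_length_6(self):
        """All sorted p-vectors on the 0.05 grid, lengths 1-6, match the
        brute-force oracle; permutation invariance covers unsorted input."""
        grid = [round(0.05 * k, 10) for k in range(21)]
        rng = np.random.default_rng(0)
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, m):
                adj, _ = bh_adjust(list(combo))
                assert np.allclose(adj, bh_oracle(list(combo)), atol=1e-12)
        # unsorted spot checks: BH commutes with permutation
        for _ in range(200):
            p = rng.random(6)
            perm = rng.permutation(6)
            adj = bh_adjust(p)[0]
            adj_perm = bh_adjust(p[perm])[0]
            assert np.allclose(adj[perm], adj_perm)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500)
        adj, sig = bh_adjust(p)
        ref_sig, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, ref_adj)
        assert np.array_equal(sig, ref_sig)

    def test_significance_is_prefix_of_sorted_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(100) ** 3
        adj, sig = bh_adjust(p)
        order = np.argsort(p)
        flags = sig[order]
        # downward-closed: once False, never True again
        assert not np.any(np.diff(flags.astype(int)) > 0)
        assert np.all(adj >= p - 1e-15)


class TestVolcano:
    def test_neg_log10_axis(self):
        sim = gen_proteomics(SimConfig(seed=0, n_proteins=50, missing_max=0.0))
        params = PipelineParams(seed=0)
        res = finalize(moderated_t(impute(preprocess(sim.matrix, params), params)))
        tab = volcano_table(res)
        row = tab.iloc[0]
        assert row.neg_log10_p_adj == pytest.approx(-np.log10(row.p_adj))
        assert tab.p_adj.is_monotonic_increasing

    def test_spike_in_recovery_single_run(self):
        """Five 2-log2-unit down-shifted proteins among 1000 all reach 5% FDR."""
        sim = gen_proteomics(SimConfig(seed=23, missing_max=0.0))
        tab = run_pipeline(sim.matrix, PipelineParams(seed=23))
        sig = set(tab.loc[tab.significant, "protein"])
        spiked = set(sim.truth.loc[sim.truth.spiked, "protein"])
        assert spiked <= sig

    def test_null_effect_yields_fdr_control(self):
        """No spike: averaged over seeds, false positives stay near the
        nominal 5% of discoveries (i.e. essentially none among pure nulls)."""
        fp = 0
        for seed in range(10):
            sim = gen_proteomics(
                SimConfig(seed=seed, spike_effect=0.0, missing_max=0.0)
            )
            tab = run_pipeline(sim.matrix, PipelineParams(seed=seed))
            fp += int(tab.significant.sum())
        assert fp / 10 <= 1.0


def test_prior_estimator_recovers_known_hyperparameters():
    """Gene variances drawn from the scaled inverse-chi-square prior:
    method-of-moments recovers (d0, s0^2) approximately."""
    rng = np.random.default_rng(9)
    d0_true, s0_true, df = 8.0, 0.25, 6
    n = 20000
    sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=n)
    s2 = sigma2 * rng.chisquare(df, size=n) / df
    d0, s0_2 = estimate_variance_prior(s2, df)
    assert d0 == pytest.approx(d0_true, rel=0.15)
    assert s0_2 == pytest.approx(s0_true, rel=0.05)
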