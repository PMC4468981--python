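"""Bayes-factor machinery vs independent numerical-integration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from searchprime import bayes
from searchprime.bayes import (ModelSpec, PriorScales, anova_bf,
                               effect_posterior, log_marginal, model_set,
                               regression_bf, sequential_stop,
                               ttest_bf_onesided)
from searchprime.bayes import _term_block


# --- oracle: dense-matrix marginal likelihood, quadrature over g ----------

def dense_logm_given_g(y, blocks, g_terms):
    """Reference m(y|g) using full n x n matrices (no Woodbury shortcut)."""
    n = len(y)
    X = np.hstack(blocks)
    g = np.concatenate([np.full(b.shape[1], gt)
                        for b, gt in zip(blocks, g_terms)])
    V = np.eye(n) + (X * g) @ X.T
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    q = y @ Vi @ y - (one @ Vi @ y) ** 2 / (one @ Vi @ one)
    _, logdet = np.linalg.slogdet(V)
    return (gammaln((n - 1) / 2) - (n - 1) / 2 * np.log(np.pi)
            - 0.5 * logdet - 0.5 * np.log(one @ Vi @ one)
            - (n - 1) / 2 * np.log(q))


def g_prior_pdf(g, r):
    return stats.invgamma.pdf(g, 0.5, scale=r ** 2 / 2)


def oracle_log_marginal(df, model, shift=20.0):
    y = df["zrt_corrected"].to_numpy()
    blocks = [_term_block(df, t) for t in model.fixed_terms + model.random_terms]
    scales = [0.5] * len(model.fixed_terms) + [1.0] * len(model.random_terms)

    if len(blocks) == 1:
        f = lambda g: (np.exp(dense_logm_given_g(y, blocks, [g]) + shift)
                       * g_prior_pdf(g, scales[0]))
        val, err = integrate.quad(f, 0, np.inf, limit=300)
    elif len(blocks) == 2:
        f = lambda g1, g2: (np.exp(dense_logm_given_g(y, blocks, [g1, g2]) + shift)
                            * g_prior_pdf(g1, scales[0]) * g_prior_pdf(g2, scales[1]))
        val, err = integrate.dblquad(f, 0, np.inf, 0, np.inf,
                                     epsabs=1e-13, epsrel=1e-9)
    else:
        raise NotImplementedError
    assert err < 1e-6 * val
    return np.log(val) - shift


class TestOracleEquivalence:
    def test_marginal_matches_quadrature_m1(self, toy_anova_data):
        m1 = model_set("exp1a")["M1"]
        oracle = oracle_log_marginal(toy_anova_data, m1)
        lm, se, _ = log_marginal(toy_anova_data, m1, n_samples=20000, seed=3)
        assert lm == pytest.approx(oracle, abs=max(3 * se, 1e-3))

    def test_marginal_matches_quadrature_null(self, toy_anova_data):
        mnull = model_set("exp1a")["Mnull"]
        oracle = oracle_log_marginal(toy_anova_data, mnull)
        lm, se, _ = log_marginal(toy_anova_data, mnull, n_samples=20000, seed=4)
        assert lm == pytest.approx(oracle, abs=max(3 * se, 1e-3))

    def test_bf_matches_oracle(self, toy_anova_data):
        models = model_set("exp1a")
        o = (oracle_log_marginal(toy_anova_data, models["M1"])
             - oracle_log_marginal(toy_anova_data, models["Mnull"]))
        bf = anova_bf(toy_anova_data, models["M1"], models["Mnull"],
                      n_samples=20000, seed=7)
        assert bf.log_bf == pytest.approx(o, abs=max(3 * bf.mc_se, 1e-3))


class TestBfAlgebra:
    def test_self_comparison_exactly_zero(self, toy_anova_data):
        m1 = model_set("exp1a")["M1"]
        assert anova_bf(toy_anova_data, m1, m1).log_bf == 0.0

    def test_antisymmetry_and_transitivity(self, small_corrected):
        data = bayes.analysis_table(small_corrected[0])
        models = model_set("exp1b")
        kw = dict(n_samples=3000, seed=2)
        ab = anova_bf(data, models["M1"], models["M2"], **kw)
        ba = anova_bf(data, models["M2"], models["M1"], **kw)
        assert ab.log_bf == pytest.approx(-ba.log_bf, abs=3 * (ab.mc_se + ba.mc_se))
        ac = anova_bf(data, models["M1"], models["M4"], **kw)
        bc = anova_bf(data, models["M2"], models["M4"], **kw)
        assert ac.log_bf == pytest.approx(ab.log_bf + bc.log_bf,
                                          abs=3 * (ab.mc_se + bc.mc_se + ac.mc_se))

    def test_scale_invariance(self, toy_anova_data):
        """Standardized-effect priors make BFs invariant to RT rescaling."""
        models = model_set("exp1a")
        a = anova_bf(toy_anova_data, models["M1"], models["Mnull"],
                     n_samples=8000, seed=5)
        scaled = toy_anova_data.assign(
            zrt_corrected=toy_anova_data["zrt_corrected"] * 37.0)
        b = anova_bf(scaled, models["M1"], models["Mnull"],
                     n_samples=8000, seed=6)
        assert a.log_bf == pytest.approx(b.log_bf, abs=3 * (a.mc_se + b.mc_se))

    def test_evidence_grows_with_n(self):
        """A true repetition effect accrues evidence as participants are
        added (consistency on an 8/16/32 ladder)."""
        rng = np.random.default_rng(12)
        rows = []
        for p in range(32):
            for rep in ("repetition", "switch"):
                for _ in range(6):
                    rows.append({
                        "participant": p, "repetition_type": rep,
                        "target_type": "bias_color",
                        "zrt_corrected": rng.standard_normal()
                        + (0.0 if rep == "repetition" else 0.5)})
        full = pd.DataFrame(rows)
        models = model_set("exp1a")
        logbfs = [anova_bf(full[full["participant"] < n_p],
                           models["M1"], models["Mnull"],
                           n_samples=4000, seed=n_p).log_bf
                  for n_p in (8, 16, 32)]
        assert logbfs[0] < logbfs[1] < logbfs[2]

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({
            "participant": [0, 0, 1, 1],
            "repetition_type": ["repetition", "switch"] * 2,
            # target perfectly aliased with repetition
            "target_type": ["bias_color", "other_color"] * 2,
            "zrt_corrected": [0.1, 0.5, -0.2, 0.4],
        })
        m2 = model_set("exp1a")["M2"]
        with pytest.raises(ValueError, match="aliased"):
            log_marginal(df, m2, n_samples=100, seed=0)


class TestEffectPosterior:
    def test_null_data_covers_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(12):
            for tt in ("bias_color", "other_color"):
                for rep in ("repetition", "switch"):
                    for _ in range(10):
                        rows.append({"participant": p, "target_type": tt,
                                     "repetition_type": rep,
                                     "zrt_corrected": rng.standard_normal()})
        df = pd.DataFrame(rows)
        m2 = model_set("exp1a")["M2"]
        post = effect_posterior(df, m2, "target", n_samples=4000, seed=1)
        assert post.ci_low < 0 < post.ci_high
        assert abs(post.mean) < 0.15

    def test_unknown_contrast_rejected(self, toy_anova_data):
        m1 = model_set("exp1a")["M1"]
        with pytest.raises(ValueError, match="not in model"):
            effect_posterior(toy_anova_data, m1, "target")

    def test_interval_brackets_mean(self, small_corrected):
        data = bayes.analysis_table(small_corrected[0])
        m2 = model_set("exp1b")["M2"]
        post = effect_posterior(data, m2, "repetition", n_samples=4000, seed=9)
        assert post.ci_low <= post.mean <= post.ci_high


class TestTTest:
    def test_matches_gspace_oracle(self):
        """Delta-space integration equals the classic g-space JZS formula."""
        rng = np.random.default_rng(0)
        x = rng.normal(0.12, 0.10, 26)
        res = ttest_bf_onesided(x)
        t, n, v = res["t"], res["n"], res["n"] - 1
        r = np.sqrt(2) / 2

        def num(g):
            return ((1 + n * g) ** -0.5
                    * (1 + t ** 2 / ((1 + n * g) * v)) ** (-(v + 1) / 2)
                    * stats.invgamma.pdf(g, 0.5, scale=r ** 2 / 2))
        m1, _ = integrate.quad(num, 0, np.inf, limit=300)
        oracle = np.log(m1) - np.log((1 + t ** 2 / v) ** (-(v + 1) / 2))
        assert res["log_bf_two_sided"] == pytest.approx(oracle, abs=1e-6)

    def test_strong_positive_scores(self):
        rng = np.random.default_rng(1)
        res = ttest_bf_onesided(rng.normal(0.12, 0.10, 26))
        assert res["log_bf"] > np.log(10)

    def test_symmetric_scores_favor_null(self):
        x = np.concatenate([np.linspace(-1, 1, 40)])
        res = ttest_bf_onesided(x)
        assert res["log_bf"] < 0

    def test_t_zero_matches_known_value(self):
        x = np.array([-1.0, 0.0, 1.0] * 10)
        res = ttest_bf_onesided(x)
        # at t=0 the one-sided and two-sided BFs coincide
        assert res["log_bf"] == pytest.approx(res["log_bf_two_sided"], abs=1e-8)
        assert res["log_bf"] < 0

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            ttest_bf_onesided([0.2, 0.2, 0.2, 0.2])


class TestRegression:
    def test_strong_slope_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.01, size=30)
        assert regression_bf(x, y).log_bf > np.log(10)

    def test_independent_data_favor_null_on_average(self):
        logs = []
        for s in range(25):
            rng = np.random.default_rng(100 + s)
            logs.append(regression_bf(rng.normal(size=30),
                                      rng.normal(size=30)).log_bf)
        assert np.mean(logs) < 0

    def test_zero_variance_predictor_errors(self):
        with pytest.raises(ValueError):
            regression_bf([1.0] * 10, np.arange(10.0))


class TestSequentialStop:
    def test_threshold_one_stops_immediately(self, small_corrected):
        data = small_corrected[0]
        res = sequential_stop([data], "exp1b", threshold=1.0,
                              n_samples=1500, seed=3)
        assert res["status"] == "stopped"
        assert res["n_batches"] == 1

    def test_exhausted_stream_inconclusive(self, small_corrected):
        data = small_corrected[0]
        sub = data[data["participant"] < 3]
        res = sequential_stop([sub], "exp1b", threshold=1e9,
                              n_samples=1000, seed=4)
        assert res["status"] == "inconclusive"
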