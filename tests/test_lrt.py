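"""Likelihood, MLE, LRT statistic, Monte-Carlo p-values, FDR and Fisher."""

import math

import numpy as np
import pytest
from scipy import stats

from dnmload.lrt import (
    GeneCohortData,
    NullSampler,
    bh_fdr,
    fisher_combine,
    log_likelihood,
    loglik_null,
    lrt_statistic,
    mc_pvalue,
    mle_r,
    test_gene as gene_test,
)


def cohort(pn, pd_, m=1e-6, n=4000, t=1000, k_by=None):
    return GeneCohortData(
        gene_id="g",
        t_individuals=t,
        n=n,
        m=m,
        pr_null=np.asarray(pn, dtype=float),
        pr_damaging=np.asarray(pd_, dtype=float),
        k_by_individual=k_by or {},
    )


def random_cohort(rng, max_k=6):
    k = int(rng.integers(1, max_k))
    return cohort(
        pn=rng.uniform(1e-4, 0.2, k),
        pd_=rng.uniform(1e-4, 0.4, k),
        m=10 ** rng.uniform(-8, -5),
        n=int(rng.integers(600, 6000)),
        t=int(rng.integers(50, 20000)),
    )


def oracle_max_loglik(data):
    """Dense grid over r plus bounded local refinement (independent path)."""
    from scipy.optimize import minimize_scalar

    r_max = 0.99 * (1.0 - data.m) / data.m
    grid = np.concatenate([[0.0], np.logspace(-6, np.log10(min(r_max, 1e6)), 3000)])
    lls = np.array([log_likelihood(data, r) for r in grid])
    j = int(np.argmax(lls))
    best = lls[j]
    if j > 0:
        lo, hi = grid[j - 1], grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda r: -log_likelihood(data, r),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-13},
        )
        best = max(best, -res.fun)
    return best


class TestLogLikelihood:
    def test_zero_events_closed_form(self):
        d = cohort([], [], m=1e-6, n=4000, t=1000)
        assert log_likelihood(d, 0.0) == pytest.approx(1000 * 4000 * math.log(1 - 1e-6))

    def test_null_form_matches_paperless_sum(self):
        """ln L(0) = ln(1-m) sum(n-k_i) + sum ln(m Pr(AAS|N))."""
        rng = np.random.default_rng(1)
        d = random_cohort(rng)
        want = d.exponent_sum * math.log(1 - d.m) + np.sum(
            np.log(d.m * d.pr_null)
        )
        assert loglik_null(d) == pytest.approx(want, rel=1e-9)

    def test_one_event_symbolic_identity(self):
        """With Pr(AAS|D) = 2 Pr(AAS|N):
        ln L(1) - ln L(0) = ln 3 + (n t - 1) [ln(1-2m) - ln(1-m)]."""
        m, n, t = 1e-5, 4000, 500
        d = cohort([0.01], [0.02], m=m, n=n, t=t)
        got = log_likelihood(d, 1.0) - log_likelihood(d, 0.0)
        want = math.log(3) + (n * t - 1) * (math.log(1 - 2 * m) - math.log(1 - m))
        assert got == pytest.approx(want, rel=1e-10)

    def test_domain_error(self):
        d = cohort([0.1], [0.1], m=1e-3)
        with pytest.raises(ValueError):
            log_likelihood(d, 1000.0)
        with pytest.raises(ValueError):
            log_likelihood(d, -0.5)


def test_score_and_hessian_match_finite_differences():
    """The analytic log-scale derivatives used by Newton-Raphson agree with
    finite differences of the log-likelihood."""
    rng = np.random.default_rng(2)
    for _ in range(20):
        d = random_cohort(rng)
        t0 = rng.uniform(-2, 2)
        r = math.exp(t0)
        a = d.m * d.pr_null
        b = d.m * d.pr_damaging
        S = d.exponent_sum
        om = 1 - d.m * (1 + r)
        g_r = -d.m * S / om + np.sum(b / (a + r * b))
        score = r * g_r
        hess = score + r * r * (
            -(d.m**2) * S / om**2 - np.sum((b / (a + r * b)) ** 2)
        )
        h = 1e-4
        f = lambda t: log_likelihood(d, math.exp(t))
        fd_score = (f(t0 + h) - f(t0 - h)) / (2 * h)
        fd_hess = (f(t0 + h) - 2 * f(t0) + f(t0 - h)) / h**2
        assert score == pytest.approx(fd_score, rel=1e-4, abs=1e-6)
        assert hess == pytest.approx(fd_hess, rel=1e-3, abs=1e-4)


class TestMLE:
    def test_zero_events_boundary(self):
        d = cohort([], [])
        r_hat, ll = mle_r(d)
        assert r_hat == 0.0 and ll == loglik_null(d)

    def test_beats_dense_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            d = random_cohort(rng)
            _, ll_alt = mle_r(d)
            assert ll_alt >= oracle_max_loglik(d) - 1e-6

    def test_all_weights_below_one_gives_zero(self):
        # damaging mass lower than neutral everywhere: null preferred
        d = cohort([0.2, 0.3], [0.002, 0.003], m=1e-6, t=10000)
        r_hat, _ = mle_r(d)
        assert lrt_statistic(d) == 0.0 and r_hat == 0.0


class TestLRTStatistic:
    def test_zero_events_zero(self):
        assert lrt_statistic(cohort([], [])) == 0.0

    def test_relabeling_invariance(self):
        pn, pd_ = [0.01, 0.02, 0.05], [0.1, 0.04, 0.2]
        d1 = cohort(pn, pd_, k_by={"a": 1, "b": 2})
        d2 = cohort(pn, pd_, k_by={"a": 2, "b": 1})
        d3 = cohort(pn, pd_, k_by={"x": 3})
        assert lrt_statistic(d1) == lrt_statistic(d2) == lrt_statistic(d3)

    def test_toy_cohort_matches_oracle(self):
        d = cohort([0.01], [0.1], m=1e-6, n=4000, t=1000)
        want = 2 * (oracle_max_loglik(d) - loglik_null(d))
        assert lrt_statistic(d) == pytest.approx(want, abs=1e-7)

    def test_adding_high_weight_event_never_decreases_d(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = random_cohort(rng)
            base = lrt_statistic(d)
            pn_new = float(rng.uniform(1e-4, 0.1))
            grown = cohort(
                np.append(d.pr_null, pn_new),
                np.append(d.pr_damaging, pn_new * rng.uniform(1.0, 10.0)),
                m=d.m,
                n=d.n,
                t=d.t_individuals,
            )
            assert lrt_statistic(grown) >= base - 1e-9

    def test_increasing_weight_never_decreases_d(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = random_cohort(rng)
            base = lrt_statistic(d)
            pd2 = d.pr_damaging.copy()
            pd2[0] *= 1.5
            assert lrt_statistic(cohort(d.pr_null, pd2, d.m, d.n, d.t_individuals)) >= base - 1e-9


class TestMCPValue:
    def test_d_zero_gives_p_one(self, engine):
        d = cohort([], [], m=engine.spectrum.m, n=engine.spectrum.n, t=100)
        p, n1 = mc_pvalue(d, engine.sampler, n_sims=99, seed=1)
        assert p == 1.0

    def test_formula_extreme_event(self, engine):
        """An astronomically weighted event is never matched by null draws:
        p = (0 + 1) / (n_sims + 1) exactly."""
        d = cohort(
            [1e-6], [1e3 * 1e-6 * 1e9], m=engine.spectrum.m, n=engine.spectrum.n, t=10000
        )
        # force an enormous observed statistic via the weight ratio
        p, n1 = mc_pvalue(d, engine.sampler, n_sims=999, seed=2)
        assert n1 == 0 and p == pytest.approx(1 / 1000)

    def test_determinism(self, engine):
        d = cohort([0.01], [0.05], m=engine.spectrum.m, n=engine.spectrum.n, t=10000)
        p1, _ = mc_pvalue(d, engine.sampler, n_sims=499, seed=42)
        p2, _ = mc_pvalue(d, engine.sampler, n_sims=499, seed=42)
        assert p1 == p2

    def test_adaptive_stop_never_anticonservative(self, engine):
        d = cohort([0.05], [0.06], m=engine.spectrum.m, n=engine.spectrum.n, t=50000)
        p_full, _ = mc_pvalue(d, engine.sampler, n_sims=4999, seed=3)
        p_adapt, n1 = mc_pvalue(
            d, engine.sampler, n_sims=4999, seed=3, adaptive_stop=True
        )
        assert p_adapt >= p_full - 0.05  # early exit only rounds the p up

    def test_null_pvalues_calibrated_on_grid(self, engine):
        """Replicates generated under the null give p-values that are
        superuniform everywhere and tight at the usual levels, honoring the
        discreteness of the Monte-Carlo grid."""
        rng = np.random.default_rng(6)
        t = 200_000
        n_sims, reps = 99, 600
        ks, idx = engine.sampler.simulate_counts(rng, reps, t)
        d_obs, _ = engine.sampler.statistics_from_atoms(ks, idx, t)
        ks2, idx2 = engine.sampler.simulate_counts(rng, reps * n_sims, t)
        d_star, _ = engine.sampler.statistics_from_atoms(ks2, idx2, t)
        n1 = (d_star.reshape(reps, n_sims) >= d_obs[:, None] - 1e-12).sum(axis=1)
        p = (n1 + 1) / (n_sims + 1)
        for alpha in (0.01, 0.02, 0.05, 0.1, 0.2, 0.5):
            achieved = np.mean(p <= alpha + 1e-12)
            se = math.sqrt(alpha * (1 - alpha) / reps)
            assert achieved <= alpha + 4 * se  # never anti-conservative
        achieved_05 = np.mean(p <= 0.05 + 1e-12)
        assert abs(achieved_05 - 0.05) <= 0.03  # tight at the working level


class TestGeneResult:
    def test_boundary_iff_d_zero(self, engine):
        d = cohort([], [], m=engine.spectrum.m, n=engine.spectrum.n, t=100)
        res = gene_test(d, engine.sampler, n_sims=99, seed=1)
        assert res.D == 0.0 and res.r_hat == 0.0 and res.p_value == 1.0
        assert res.p_value >= 1 / (res.n_sims + 1)


class TestBHFdr:
    def test_single(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_hand_computed_three(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestFisherCombine:
    def test_identity_single(self):
        assert fisher_combine([0.05]) == pytest.approx(0.05)

    def test_two_times_point05_chi2_oracle(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert x == pytest.approx(11.9829, abs=1e-4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, 4))

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])
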