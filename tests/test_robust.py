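"""EPRCA, GLS under co-expression covariance, resampling enrichment and
the branch-/degree-preserving permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evotiss import GeneNetwork
from evotiss.datatypes import ValidationError
from evotiss.robust import (
    CoexpressionGLS,
    branch_preserving_permutation,
    degree_preserving_null,
    eprca,
    gls_fit,
    partial_spearman,
    resampling_enrichment,
)
from evotiss.simulate import block_covariance


def brute_force_partial(d, k, x):
    """Oracle: explicit ranks, pairwise Pearson on ranks, displayed formula."""
    rd, rk, rx = (stats.rankdata(v) for v in (d, k, x))
    r_dk = np.corrcoef(rd, rk)[0, 1]
    r_dx = np.corrcoef(rd, rx)[0, 1]
    r_kx = np.corrcoef(rk, rx)[0, 1]
    return (r_dk - r_dx * r_kx) / np.sqrt((1 - r_dx**2) * (1 - r_kx**2))


class TestPartialSpearman:
    def test_identical_d_k(self, rng):
        d = rng.standard_normal(50)
        x = rng.standard_normal(50)
        assert partial_spearman(d, d, x) == pytest.approx(1.0)

    def test_five_point_oracle(self):
        d = [3.0, 1.0, 4.0, 1.5, 5.0]
        k = [2.0, 7.0, 1.0, 8.0, 2.5]
        x = [9.0, 2.0, 6.0, 5.0, 3.0]
        assert partial_spearman(d, k, x) == pytest.approx(
            brute_force_partial(d, k, x)
        )

    def test_independent_inputs_near_zero(self, rng):
        d = rng.standard_normal(10_000)
        k = rng.standard_normal(10_000)
        x = rng.standard_normal(10_000)
        assert abs(partial_spearman(d, k, x)) < 0.03

    def test_degenerate_conditioner(self):
        d = np.arange(5.0)
        with pytest.raises(ValidationError):
            partial_spearman(d, d[::-1], d)  # |r_DX| = 1

    def test_too_short(self):
        with pytest.raises(ValidationError):
            partial_spearman([1, 2, 3], [3, 2, 1], [1, 3, 2])


class TestEPRCA:
    def test_joint_shuffle_preserves_d_x_correlation(self, rng):
        """The permutation scheme keeps Spearman(D, X') exactly fixed."""
        d = rng.standard_normal(200)
        x = 0.5 * d + rng.standard_normal(200)
        base = stats.spearmanr(d, x).statistic
        for seed in range(5):
            p = np.random.default_rng(seed).permutation(200)
            assert stats.spearmanr(d[p], x[p]).statistic == pytest.approx(
                base, abs=1e-12
            )

    def test_full_independence_null_calibrated(self, rng):
        """D independent of K: empirical p uniform, rejection near 5%."""
        ps = []
        for i in range(200):
            x = rng.standard_normal(300)
            d = x + rng.standard_normal(300)
            xn = x + rng.standard_normal(300)
            k = rng.standard_normal(300)
            ps.append(eprca(d, k, xn, n_perm=100, seed=i).empirical_p)
        ps = np.array(ps)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert 0.01 <= np.mean(ps < 0.05) <= 0.11

    def test_noiseless_conditional_independence(self, rng):
        """With the true X as conditioner the test is calibrated and theta
        stays near zero."""
        ps, thetas = [], []
        for i in range(200):
            x = rng.standard_normal(500)
            d = x + rng.standard_normal(500)
            k = x + rng.standard_normal(500)
            res = eprca(d, k, x, n_perm=200, seed=i)
            ps.append(res.empirical_p)
            thetas.append(res.theta_adj)
        # under the null theta ~ |r_obs|, whose mean is sqrt(2/pi)/sqrt(n-3)
        # ~= 0.036 at n = 500; assert it stays at that sampling-noise floor
        assert np.mean(thetas) < 0.05
        assert 0.005 <= np.mean(np.array(ps) < 0.05) <= 0.12

    def test_theta_recovers_partial_correlation(self, rng):
        """theta ~= rho_true for D carrying an independent effect."""
        rho = 0.2
        thetas = []
        for i in range(60):
            x = rng.standard_normal(800)
            e1 = rng.standard_normal(800)
            d = e1
            k = x + rho * e1 + np.sqrt(1 - rho**2) * rng.standard_normal(800)
            thetas.append(eprca(d, k, x, n_perm=200, seed=i).theta_adj)
        assert abs(np.mean(thetas) - rho) < 0.05

    def test_small_n_perm_warns(self, rng):
        d, k, x = (rng.standard_normal(30) for _ in range(3))
        with pytest.warns(UserWarning):
            eprca(d, k, x, n_perm=50, seed=0)


class TestGLS:
    def test_hand_example(self):
        """dN=(1,2), G=(1,1), Delta=[[1,.5],[.5,1]] -> pi_hat = 0.5 via
        Delta^-1 = [[4/3,-2/3],[-2/3,4/3]]."""
        fit = gls_fit([1.0, 1.0], [1.0, 2.0], [[1.0, 0.5], [0.5, 1.0]])
        assert fit.pi_hat == pytest.approx(0.5, abs=1e-12)

    def test_identity_reduces_to_ols(self, rng):
        dn = rng.uniform(0.1, 1.0, 60)
        g = 0.7 * dn + rng.standard_normal(60)
        fit = gls_fit(g, dn, np.eye(60))
        ols = float(dn @ g / (dn @ dn))
        assert abs(fit.pi_hat - ols) <= 1e-10 * abs(ols)

    def test_matches_explicit_inverse(self, rng):
        n = 30
        delta = block_covariance(n, 6, 0.5)
        dn = rng.uniform(0.1, 1.0, n)
        g = 0.3 * dn + rng.standard_normal(n)
        fit = gls_fit(g, dn, delta)
        inv = np.linalg.inv(delta)
        explicit = (dn @ inv @ g) / (dn @ inv @ dn)
        assert fit.pi_hat == pytest.approx(explicit, rel=1e-10)
        assert fit.var_pi_hat == pytest.approx(
            fit.sigma2_hat / (dn @ inv @ dn), rel=1e-10
        )

    def test_exact_fit_invariance(self, rng):
        dn = rng.uniform(0.1, 1.0, 25)
        delta = block_covariance(25, 5, 0.4)
        fit = gls_fit(3.5 * dn, dn, delta)
        assert fit.pi_hat == pytest.approx(3.5, abs=1e-10)

    def test_non_pd_reports_failing_minor(self):
        bad = np.eye(4)
        bad[2, 2] = -1.0
        with pytest.raises(ValidationError, match="leading minor 3"):
            gls_fit(np.ones(4), np.ones(4), bad)

    def test_zero_dn_rejected(self):
        with pytest.raises(ValidationError):
            gls_fit(np.ones(3), np.zeros(3), np.eye(3))

    def test_gls_beats_ols_under_block_noise(self):
        """Sampling variance of the GLS estimate never exceeds OLS when the
        noise really is block-correlated."""
        n = 100
        delta = block_covariance(n, 20, 0.7)
        chol = np.linalg.cholesky(delta)
        master = np.random.default_rng(5)
        dn = master.uniform(0.1, 1.0, n)
        gls_est, ols_est = [], []
        for _ in range(300):
            g = 0.5 * dn + chol @ master.standard_normal(n)
            gls_est.append(gls_fit(g, dn, delta).pi_hat)
            ols_est.append(gls_fit(g, dn, np.eye(n)).pi_hat)
        assert np.var(gls_est) <= np.var(ols_est)

    def test_estimator_class_api(self, rng):
        dn = rng.uniform(0.1, 1.0, 40)
        g = 0.9 * dn + 0.1 * rng.standard_normal(40)
        est = CoexpressionGLS().fit(dn.reshape(-1, 1), g)
        assert est.pi_hat_ == pytest.approx(float(dn @ g / (dn @ dn)))
        np.testing.assert_allclose(est.predict(dn.reshape(-1, 1)), est.pi_hat_ * dn)
        assert "delta" in est.get_params()


class TestResamplingEnrichment:
    def test_property_everywhere_gives_p_one(self):
        genes = [f"g{i}" for i in range(50)]
        prop = pd.Series(True, index=genes)
        res = resampling_enrichment(genes[:10], genes, prop, n_draws=200, seed=0)
        assert res.observed == 10 and res.empirical_p == 1.0

    def test_random_target_is_null(self, rng):
        genes = pd.Index([f"g{i}" for i in range(400)])
        prop = pd.Series(rng.random(400) < 0.3, index=genes)
        ps = [
            resampling_enrichment(
                rng.choice(genes, 50, replace=False), genes, prop,
                n_draws=200, seed=i,
            ).empirical_p
            for i in range(150)
        ]
        # discrete null: check the rejection rate rather than exact uniformity
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.10
        assert np.mean(ps) > 0.35

    def test_enriched_target_detected(self, rng):
        genes = pd.Index([f"g{i}" for i in range(5000)])
        prop = pd.Series(rng.random(5000) < 0.2, index=genes)
        weights = np.where(prop, 2.0, 1.0)
        pick = rng.choice(
            genes, 500, replace=False, p=weights / weights.sum()
        )
        res = resampling_enrichment(pick, genes, prop, n_draws=1000, seed=1)
        assert res.empirical_p == 0.0

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            resampling_enrichment(["zz"], ["g1"], pd.Series({"g1": True}))


class TestBranchNull:
    def test_single_group_matches_unrestricted(self, rng):
        """One branch group is distributionally an unrestricted shuffle."""
        omega = rng.lognormal(size=300)
        cov = rng.standard_normal(300)
        stat = lambda om: float(stats.spearmanr(om, cov).statistic)
        one = branch_preserving_permutation(
            omega, np.zeros(300), stat, n_perm=2000, seed=1
        )
        free = np.array(
            [
                stat(np.random.default_rng(10_000 + i).permutation(omega))
                for i in range(2000)
            ]
        )
        assert stats.ks_2samp(one.null_values, free).pvalue > 0.01

    def test_every_gene_its_own_group_is_identity(self, rng):
        omega = rng.lognormal(size=40)
        cov = rng.standard_normal(40)
        stat = lambda om: float(stats.spearmanr(om, cov).statistic)
        res = branch_preserving_permutation(
            omega, np.arange(40), stat, n_perm=100, seed=2
        )
        assert np.all(res.null_values == res.observed)
        assert res.empirical_p == 1.0

    def test_within_branch_null_calibrated(self, rng):
        ps = []
        for i in range(100):
            branches = rng.choice(["b0", "b1", "b2"], size=200)
            omega = rng.lognormal(size=200)
            cov = rng.standard_normal(200)
            stat = lambda om: abs(stats.spearmanr(om, cov).statistic)
            ps.append(
                branch_preserving_permutation(
                    omega, branches, stat, n_perm=100, seed=i
                ).empirical_p
            )
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_statistic_failure_annotated(self, rng):
        calls = {"n": 0}

        def bad(om):
            calls["n"] += 1
            if calls["n"] > 1:  # fail on the first permuted replicate
                raise ValueError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="permutation 0"):
            branch_preserving_permutation(
                rng.lognormal(size=10), np.zeros(10), bad, n_perm=3, seed=0
            )


def _random_network(rng, n=60, p=0.08):
    import networkx as nx

    g = nx.gnp_random_graph(n, p, seed=7)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})
    return GeneNetwork(g)


class TestDegreeNull:
    def test_rewire_preserves_degree_sequence(self, rng):
        net = _random_network(rng)
        omega = pd.Series(rng.lognormal(size=len(net.nodes)), index=net.nodes)
        seen = []

        def stat(network, om):
            seen.append(tuple(network.degree_sequence()))
            return 0.0

        degree_preserving_null(net, omega, stat, n_perm=10, seed=0, mode="rewire")
        base = tuple(net.degree_sequence())
        assert all(s == base for s in seen)

    def test_rewire_changes_topology(self, rng):
        net = _random_network(rng)
        omega = pd.Series(rng.lognormal(size=len(net.nodes)), index=net.nodes)

        def edge_fingerprint(network, om):
            return float(hash(frozenset(map(frozenset, network.graph.edges))) % 997)

        res = degree_preserving_null(
            net, omega, edge_fingerprint, n_perm=5, seed=1, mode="rewire"
        )
        assert len(set(res.null_values)) > 1

    def test_triangle_has_unique_configuration(self, rng):
        """The triangle is the only simple graph on its degree sequence, so
        every rewired statistic equals the observed one and p = 1."""
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        omega = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])

        def stat(network, om):
            deg = network.degree_series().reindex(om.index)
            return float((deg * om).sum())

        res = degree_preserving_null(net, omega, stat, n_perm=30, seed=0, mode="rewire")
        assert np.all(res.null_values == res.observed)
        assert res.empirical_p == 1.0

    def test_strata_null_width_grows_with_bin_width(self, rng):
        """Fine degree strata pin Spearman(degree, omega) near the observed
        value; merging all strata widens the null."""
        net = _random_network(rng, n=120, p=0.06)
        nodes = pd.Index(net.nodes)
        deg = net.degree_series().reindex(nodes)
        omega = pd.Series(
            -0.5 * deg.to_numpy() + rng.standard_normal(len(nodes)), index=nodes
        )

        def stat(network, om):
            d = network.degree_series().reindex(om.index)
            return float(stats.spearmanr(d, om).statistic)

        fine = degree_preserving_null(
            net, omega, stat, n_perm=150, seed=2, mode="strata"
        )
        # coarse limit: a single stratum, i.e. an unrestricted shuffle
        one_bin = branch_preserving_permutation(
            omega.to_numpy(),
            np.zeros(len(nodes)),
            lambda om: float(stats.spearmanr(deg.to_numpy(), om).statistic),
            n_perm=150,
            seed=2,
        )
        assert fine.null_sd < one_bin.null_sd
        assert abs(fine.null_mean - fine.observed) < abs(
            one_bin.null_mean - fine.observed
        )

    def test_missing_omega_rejected(self, rng):
        net = _random_network(rng)
        omega = pd.Series([1.0], index=["g0"])
        with pytest.raises(ValidationError):
            degree_preserving_null(net, omega, lambda n, o: 0.0, n_perm=2)
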