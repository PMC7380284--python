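"""Tissue-anchored model: Kruskal-Wallis machinery, the gene-count-
preserving permutation null, MaxTissue-delta and the overlap test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evotiss.anchor import (
    affected_tissue_overlap,
    anchor_test,
    kruskal_h,
    max_tissue_association,
    max_tissue_delta,
    max_tissue_permutation,
    tissue_signature,
)
from evotiss.datatypes import ValidationError


def brute_force_h(groups):
    """Oracle: H from explicit rank sums on the pooled observations."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(t**3 - t) / (n**3 - n))


class TestKruskal:
    def test_two_group_oracle(self):
        """(1,2,3) vs (4,5,6): H from exhaustive rank computation."""
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6])]
        expected = brute_force_h(groups)  # = 27/7
        labels = ["a"] * 3 + ["b"] * 3
        h, _ = kruskal_h(labels, np.concatenate(groups))
        assert expected == pytest.approx(27 / 7)
        assert h == pytest.approx(expected)

    def test_matches_scipy_with_ties(self, rng):
        values = rng.integers(0, 10, size=120).astype(float)
        labels = rng.choice(["a", "b", "c"], size=120)
        h, _ = kruskal_h(labels, values)
        groups = [values[labels == g] for g in ("a", "b", "c")]
        assert h == pytest.approx(stats.kruskal(*groups).statistic)

    def test_constant_values(self):
        h, p = max_tissue_association(["a", "a", "b", "b"], [1.0, 1.0, 1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_single_tissue_error(self):
        with pytest.raises(ValidationError):
            max_tissue_association(["a", "a"], [1.0, 2.0])


class TestPermutation:
    def test_constant_omega_gives_p_one(self):
        res = max_tissue_permutation(
            ["a", "b"] * 10, np.ones(20), n_perm=50, seed=0
        )
        assert res.empirical_p == 1.0

    def test_observed_matches_analytic_h(self, rng):
        values = rng.standard_normal(200)
        labels = rng.choice(["a", "b", "c", "d"], size=200)
        res = max_tissue_permutation(labels, values, n_perm=10, seed=1)
        h, _ = kruskal_h(labels, values)
        assert res.observed == pytest.approx(h)

    def test_null_calibration_and_analytic_agreement(self, rng):
        """Labels independent of omega: empirical p uniform and consistent
        with the chi-square p within Monte-Carlo error."""
        ps, pas = [], []
        for i in range(100):
            values = rng.lognormal(size=400)
            labels = rng.choice([f"t{j}" for j in range(6)], size=400)
            res = max_tissue_permutation(labels, values, n_perm=200, seed=i)
            ps.append(res.empirical_p)
            pas.append(max_tissue_association(labels, values)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        ps, pas = np.array(ps), np.array(pas)
        mc_err = 2 * np.sqrt(np.maximum(pas * (1 - pas), 0.01) / 200)
        assert np.mean(np.abs(ps - pas) < mc_err + 0.02) > 0.9

    def test_strong_shift_detected(self, rng):
        omega = np.concatenate([rng.normal(0, 1, 300), rng.normal(1.5, 1, 300)])
        labels = ["a"] * 300 + ["b"] * 300
        res = max_tissue_permutation(labels, omega, n_perm=1000, seed=3)
        assert res.empirical_p == 0.0
        assert res.resolution == pytest.approx(1 / 1000)


class TestDelta:
    def test_closed_forms(self):
        assert max_tissue_delta([0.5, 0.5, 0.5, 0.5]) == 0.0
        # v75 - v25 = 0.2, n = 4 -> 3.14 * 0.2 / 2 = 0.314
        x = [0.1, 0.1, 0.3, 0.3]
        assert max_tissue_delta(x) == pytest.approx(3.14 * 0.2 / 2)
        x100 = np.linspace(0, 1, 100)
        v75, v25 = np.percentile(x100, [75, 25])
        assert max_tissue_delta(x100) == pytest.approx(3.14 * (v75 - v25) / 10)

    @given(
        x=st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        a=st.floats(0.01, 50),
        b=st.floats(-5, 5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_affine_equivariance(self, x, a, b):
        """delta(a x + b) = a delta(x) for a > 0 (location-invariant,
        linearly scaling)."""
        x = np.asarray(x)
        assert max_tissue_delta(a * x + b) == pytest.approx(
            a * max_tissue_delta(x), rel=1e-9, abs=1e-12
        )

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            max_tissue_delta([])


class TestSignature:
    def test_medians_and_sorting(self):
        labels = ["a", "a", "a", "b"]
        omega = [0.1, 0.2, 0.3, 0.4]
        sig = tissue_signature(labels, omega)
        assert sig.loc["a", "median_omega"] == pytest.approx(0.2)
        assert sig.loc["b", "median_omega"] == pytest.approx(0.4)
        assert list(sig.index) == ["a", "b"]
        assert sig["n"].sum() == 4

    def test_leave_one_tissue_out(self, rng):
        labels = rng.choice(["a", "b", "c"], size=90)
        omega = rng.lognormal(size=90)
        res = anchor_test(labels, omega, n_perm=0, drop_tissue="c")
        assert set(res.signature.index) == {"a", "b"}
        keep = labels != "c"
        h, _ = kruskal_h(labels[keep], omega[keep])
        assert res.h_statistic == pytest.approx(h)

    def test_recovers_true_shift_order(self):
        """Simulated anchor shifts: tissue medians rank like the true
        per-tissue shifts."""
        from evotiss import SimConfig, simulate_dataset, per_tissue_moments
        from evotiss.features import max_tissue_table

        d = simulate_dataset(
            SimConfig(n_genes=5000, n_tissues=10, anchor_effect_sd=0.4, seed=21)
        )
        var = per_tissue_moments(d.expression, "raw")["variance"]
        mt = max_tissue_table(var)["max_tissue"]
        sig = tissue_signature(mt.to_numpy(), d.rates.omega.to_numpy())
        truth = d.truth["delta"].loc[sig.index]
        assert stats.spearmanr(sig["median_omega"], truth).statistic > 0.8


class TestOverlap:
    def test_perfect_dependence(self, rng):
        genes = pd.Index([f"g{i}" for i in range(200)])
        mt = pd.Series(rng.choice(["a", "b", "c"], size=200), index=genes)
        res = affected_tissue_overlap(mt, mt.copy())
        assert res.pvalue < 1e-20
        assert res.odds_ratio_infinite and np.isinf(res.match_odds_ratio)

    def test_random_affected_is_null(self, rng):
        ps = []
        for i in range(60):
            genes = pd.Index([f"g{i}" for i in range(300)])
            mt = pd.Series(rng.choice([f"t{j}" for j in range(5)], 300), index=genes)
            af = pd.Series(rng.choice([f"t{j}" for j in range(5)], 300), index=genes)
            ps.append(affected_tissue_overlap(mt, af).pvalue)
        assert np.mean(np.array(ps) < 0.05) < 0.15
        assert np.mean(ps) > 0.3

    def test_generator_p_match_signal(self, small_sim):
        """With p_match = 0.5 the realized MaxTissue strongly predicts the
        affected tissue."""
        from evotiss import build_feature_table

        ft = build_feature_table(small_sim.expression)
        res = affected_tissue_overlap(
            ft.summary["max_tissue"], small_sim.affected_tissue
        )
        assert res.pvalue < 1e-3
        assert res.match_odds_ratio > 1.5

    def test_unmatched_vocabulary_dropped(self, rng):
        genes = pd.Index([f"g{i}" for i in range(100)])
        mt = pd.Series(["weird"] * 50 + list(rng.choice(["a", "b"], 50)), index=genes)
        af = pd.Series(rng.choice(["a", "b"], size=100), index=genes)
        res = affected_tissue_overlap(mt, af)
        assert res.n_dropped == 50 and res.n_genes == 50

    def test_degenerate_table_error(self):
        genes = pd.Index(["g1", "g2"])
        mt = pd.Series(["a", "a"], index=genes)
        af = pd.Series(["a", "b"], index=genes)
        with pytest.raises(ValidationError):
            affected_tissue_overlap(mt, af)
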