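"""Linear-model plumbing: risk adjustment, ANOVA components, n', IURs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piurkit import (
    ProviderPanel,
    VarianceComponents,
    center_mu,
    estimate_beta_fixed_effects,
    estimate_variance_components,
    n_prime,
    provider_means,
    risk_adjust,
)


def make_panel(ids, y, X=None):
    return ProviderPanel(ids, np.asarray(y, float), X)


class TestNPrime:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([100] * 1000, 100.0),
            ([2, 2], 2.0),
            ([10, 50, 200], (260 - (100 + 2500 + 40000) / 260) / 2),
        ],
    )
    def test_printed_formula(self, sizes, expected):
        assert n_prime(sizes) == pytest.approx(expected, rel=1e-12)

    def test_rejects_single_provider(self):
        with pytest.raises(ValueError):
            n_prime([5])

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_upper_bounded_by_mean_size(self, sizes):
        np_eff = n_prime(sizes)
        mean = np.mean(sizes)
        assert np_eff <= mean + 1e-9
        if len(set(sizes)) == 1:
            assert np_eff == pytest.approx(mean)


class TestRiskAdjust:
    def test_identity_when_mu_zero_no_covariates(self):
        panel = make_panel(["a", "a", "b", "b"], [1.0, 2.0, 3.0, 4.0])
        adj = risk_adjust(panel, VarianceComponents(mu=0.0))
        assert np.allclose(adj.y_adjusted, adj.y_raw)

    def test_single_record_arithmetic(self):
        panel = make_panel(["a", "b"], [5.0, 0.0], X=[[2.0], [0.0]])
        adj = risk_adjust(panel, VarianceComponents(mu=1.0, beta=(1.5,)))
        # provider 'a': 5 - 1 - 2*1.5 = 1
        assert adj.y_adjusted[0] == pytest.approx(1.0)

    def test_round_trip(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        panel = make_panel([f"p{i % 8}" for i in range(40)], y, X)
        comp = VarianceComponents(mu=0.7, beta=(1.2, -0.4))
        adj = risk_adjust(panel, comp)
        back = adj.y_adjusted + comp.mu + adj.X @ np.array(comp.beta)
        assert np.allclose(back, adj.y_raw)

    def test_dimension_mismatch_errors(self):
        panel = make_panel(["a", "b"], [1.0, 2.0])
        with pytest.raises(ValueError):
            risk_adjust(panel, VarianceComponents(beta=(1.0,)))


class TestProviderMeans:
    def test_simple_means(self):
        panel = make_panel(["a", "a", "b"], [1.0, 3.0, 7.0])
        adj = risk_adjust(panel, VarianceComponents())
        means = provider_means(adj)
        assert means["a"] == pytest.approx(2.0)
        assert means["b"] == pytest.approx(7.0)

    def test_agrees_with_bruteforce_groupby(self, rng):
        ids = rng.choice([f"p{i}" for i in range(12)], size=300)
        y = rng.normal(size=300)
        adj = risk_adjust(make_panel(ids, y), VarianceComponents())
        means = provider_means(adj)
        for pid in set(ids.tolist()):
            assert means[pid] == pytest.approx(float(y[ids == pid].mean()))

    def test_requires_adjustment(self):
        with pytest.raises(ValueError):
            provider_means(make_panel(["a", "b"], [1.0, 2.0]))


class TestCenterMu:
    def test_plain_mean(self):
        panel = make_panel(["a", "b", "c"], [1.0, 2.0, 3.0])
        assert center_mu(panel, np.empty(0)) == pytest.approx(2.0)

    def test_equals_residual_mean(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        panel = make_panel([f"p{i % 6}" for i in range(60)], y, X)
        beta = np.array([0.5, -1.0])
        assert center_mu(panel, beta) == pytest.approx(float((y - X @ beta).mean()))


class TestBetaFixedEffects:
    def test_exact_within_provider_relation(self):
        # y = 2x within provider, arbitrary provider offsets
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        offs = np.array([10.0] * 3 + [-5.0] * 3)
        panel = make_panel(["a"] * 3 + ["b"] * 3, offs + 2.0 * x, x[:, None])
        beta = estimate_beta_fixed_effects(panel)
        assert beta == pytest.approx([2.0], abs=1e-10)

    def test_no_covariates_gives_empty(self):
        assert estimate_beta_fixed_effects(make_panel(["a", "b"], [1.0, 2.0])).size == 0

    def test_matches_dummy_regression_oracle(self, rng):
        # small instance: one indicator per provider must agree exactly
        m, n = 12, 8
        ids = np.repeat([f"p{i:02d}" for i in range(m)], n)
        X = rng.normal(size=(m * n, 2))
        alpha = rng.normal(size=m)
        y = np.repeat(alpha, n) + X @ np.array([1.5, -0.5]) + rng.normal(size=m * n)
        panel = make_panel(ids, y, X)
        beta = estimate_beta_fixed_effects(panel)
        dummies = np.equal.outer(ids, np.unique(ids)).astype(float)
        full = np.column_stack([X, dummies])
        coef, *_ = np.linalg.lstsq(full, y, rcond=None)
        assert beta == pytest.approx(coef[:2], abs=1e-8)

    def test_unbiased_under_confounding_where_pooled_ols_is_not(self):
        from piurkit import SimulationConfig, simulate_panel

        cfg = SimulationConfig(
            m=200, target_iur=0.5, beta=(1.5, -0.5), confounding=25.0, seed=7
        )
        panel, truth = simulate_panel(cfg)
        beta = estimate_beta_fixed_effects(panel)
        assert beta == pytest.approx([1.5, -0.5], abs=0.05)
        pooled, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(panel)), panel.X]), panel.y_raw, rcond=None
        )
        assert abs(pooled[1] - 1.5) > 3 * abs(beta[0] - 1.5)

    def test_collinear_columns_named(self, rng):
        X1 = rng.normal(size=(40, 1))
        X = np.hstack([X1, 2 * X1])
        panel = make_panel([f"p{i % 4}" for i in range(40)], rng.normal(size=40), X)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            estimate_beta_fixed_effects(panel)


class TestVarianceComponents:
    def test_all_equal_outcomes_is_degenerate(self):
        panel = make_panel(["a", "a", "b", "b"], [3.0, 3.0, 3.0, 3.0])
        adj = risk_adjust(panel, VarianceComponents())
        with pytest.raises(ValueError, match="within-provider variance"):
            estimate_variance_components(adj)

    def test_tiny_noise_gives_near_zero_iur(self, rng):
        y = 3.0 + rng.normal(0, 1e-6, size=200)
        adj = risk_adjust(make_panel([f"p{i % 20}" for i in range(200)], y), VarianceComponents())
        est = estimate_variance_components(adj)
        assert est.overall_iur < 0.2
        assert est.sigma_b2_hat >= 0.0

    def test_invariant_to_record_permutation_and_relabeling(self, rng):
        ids = np.repeat([f"p{i}" for i in range(10)], 20)
        y = rng.normal(size=200) + np.repeat(rng.normal(0, 0.5, 10), 20)
        adj = risk_adjust(make_panel(ids, y), VarianceComponents())
        est = estimate_variance_components(adj)
        perm = rng.permutation(200)
        relabeled = [f"site-{s}" for s in ids[perm]]
        adj2 = risk_adjust(make_panel(relabeled, y[perm]), VarianceComponents())
        est2 = estimate_variance_components(adj2)
        assert est2.overall_iur == pytest.approx(est.overall_iur, rel=1e-10)
        assert est2.sigma_w2_hat == pytest.approx(est.sigma_w2_hat, rel=1e-10)

    def test_iur_invariants_hold(self, null_panel_50):
        panel, _ = null_panel_50
        est = estimate_variance_components(panel)
        expect = est.sigma_b2_hat / (est.sigma_b2_hat + est.sigma_w2_hat / est.n_prime)
        assert est.overall_iur == pytest.approx(expect, rel=1e-12)
        assert 0 <= est.overall_iur < 1
        some = list(est.per_provider_iur.values())[:5]
        for v, n in zip(some, panel.sizes[:5]):
            assert v == pytest.approx(
                est.sigma_b2_hat / (est.sigma_b2_hat + est.sigma_w2_hat / n), rel=1e-12
            )

    @pytest.mark.parametrize("target", [0.25, 0.5])
    def test_parameter_recovery(self, target):
        """Mean ANOVA IUR over replicate panels lands on the target."""
        from piurkit import SimulationConfig, simulate_panel

        vals = []
        for rep in range(25):
            panel, _ = simulate_panel(
                SimulationConfig(m=500, target_iur=target, seed=None), rng_seed=3000 + rep
            )
            vals.append(estimate_variance_components(panel).overall_iur)
        assert np.mean(vals) == pytest.approx(target, abs=0.02)


class TestPanelValidation:
    def test_rejects_single_provider(self):
        with pytest.raises(ValueError):
            make_panel(["a", "a"], [1.0, 2.0])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            make_panel(["a", "b"], [1.0, np.nan])

    def test_sizes_sum_to_records(self, rng):
        ids = rng.choice(["a", "b", "c"], size=50)
        panel = make_panel(ids, rng.normal(size=50))
        assert panel.sizes.sum() == panel.n_records == 50
        assert panel.m == 3
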