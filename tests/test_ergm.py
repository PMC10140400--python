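"""ERGM: statistics, exact dyad-independent MLE, sampler, MCMC-MLE.

Oracles: hand counts on tiny graphs, the closed-form saturated three-pattern
solution, a brute-force all-dyads logistic fit (statsmodels), and analytic
stationary expectations for the tie-flip chain.
"""

import math

import numpy as np
import networkx as nx
import pytest
from scipy.special import expit, logit

from burnoutnet import ergm
from burnoutnet.ergm import (
    ErgmControl,
    ErgmError,
    ErgmSpec,
    ErgmTerm,
    burnout_spec,
    change_statistics,
    compare_models,
    dyad_pattern_design,
    fit_exact,
    fit_mcmcmle,
    mh_sampler,
    predicted_edge_probability,
    simulate_network,
    sufficient_statistics,
    zero_spec,
)


def _attrs(n, n_high, prefix="n"):
    return {f"{prefix}{i}": ("high" if i < n_high else "low")
            for i in range(n)}


def _graph(n, n_high, edges):
    g = nx.Graph()
    for node, status in _attrs(n, n_high).items():
        g.add_node(node, burnout=status)
    g.add_edges_from((f"n{i}", f"n{j}") for i, j in edges)
    return g


class TestStatistics:
    @pytest.mark.parametrize("si, sj, expected", [
        ("low", "low", (1, 0, 1)),
        ("low", "high", (1, 1, 0)),
        ("high", "high", (1, 2, 1)),
    ])
    def test_change_statistics_by_pattern(self, si, sj, expected):
        delta = change_statistics({"burnout": si}, {"burnout": sj},
                                  burnout_spec())
        assert tuple(delta) == expected

    def test_empty_graph_zero_vector(self):
        g = _graph(5, 2, [])
        assert np.all(sufficient_statistics(g, burnout_spec()) == 0)

    def test_triangle_hand_count(self):
        # triangle on (high, high, low): edges=3, endpoints at 'high'
        # across the 3 edges = 4, same-status edges = 1
        g = _graph(3, 2, [(0, 1), (1, 2), (0, 2)])
        stats = sufficient_statistics(g, burnout_spec())
        assert tuple(stats) == (3, 4, 1)

    def test_statistics_sum_change_stats_over_edges(self, rng):
        spec = burnout_spec()
        for _ in range(10):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1e6)))
            mapping = {i: f"n{i}" for i in g.nodes}
            g = nx.relabel_nodes(g, mapping)
            for i, node in enumerate(g.nodes):
                g.nodes[node]["burnout"] = "high" if i % 3 == 0 else "low"
            brute = sum(
                (change_statistics(g.nodes[u], g.nodes[v], spec)
                 for u, v in g.edges()),
                start=np.zeros(3))
            assert np.allclose(sufficient_statistics(g, spec), brute)

    def test_missing_attribute_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ErgmError, match="burnout"):
            sufficient_statistics(g, burnout_spec())

    def test_pattern_counts_cover_all_dyads(self):
        g = _graph(10, 3, [(0, 1), (4, 5)])
        design = dyad_pattern_design(g, burnout_spec())
        assert design.n_dyads.sum() == 45
        assert np.all(design.n_edges <= design.n_dyads)


class TestFitExact:
    def test_edges_only_coefficient_is_logit_density(self):
        g = _graph(20, 6, [(i, (i + 1) % 20) for i in range(20)])
        fit = fit_exact(g, zero_spec())
        density = 20 / (20 * 19 / 2)
        assert fit.coefficients[0] == pytest.approx(logit(density))

    def test_three_term_fit_equals_closed_form(self, rng):
        """The saturated 3-pattern model solves logit(p_LL)=t1+t3,
        logit(p_LH)=t1+t2, logit(p_HH)=t1+2t2+t3 exactly."""
        attrs = _attrs(120, 40)
        g = simulate_network([-1.5, -0.4, 0.6], attrs, burnout_spec(),
                             seed=17)
        fit = fit_exact(g, burnout_spec())
        design = dyad_pattern_design(g, burnout_spec())
        dens = {lbl: e / n for lbl, n, e in zip(
            design.class_labels, design.n_dyads, design.n_edges)}
        p_hh = dens[(("high",), ("high",))]
        p_lh = dens[(("high",), ("low",))]
        p_ll = dens[(("low",), ("low",))]
        a = np.array([[1, 0, 1], [1, 1, 0], [1, 2, 1]], dtype=float)
        closed = np.linalg.solve(
            a, [logit(p_ll), logit(p_lh), logit(p_hh)])
        assert np.max(np.abs(fit.coefficients - closed)) < 1e-8

    def test_collapsed_fit_equals_all_dyads_logistic(self):
        """At N=50 the pattern-collapsed Newton fit matches a brute-force
        GLM over all 1225 dyads (independent statsmodels oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        attrs = _attrs(50, 14)
        g = simulate_network([-1.0, -0.3, 0.5], attrs, burnout_spec(),
                             seed=23)
        fit = fit_exact(g, burnout_spec())
        nodes = list(g.nodes)
        rows, y = [], []
        for i in range(50):
            for j in range(i + 1, 50):
                rows.append(change_statistics(
                    g.nodes[nodes[i]], g.nodes[nodes[j]], burnout_spec()))
                y.append(1.0 if g.has_edge(nodes[i], nodes[j]) else 0.0)
        glm = sm.GLM(np.asarray(y), np.asarray(rows),
                     family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coefficients - glm.params)) < 1e-6
        assert np.max(np.abs(fit.standard_errors - glm.bse)) < 1e-5
        assert fit.loglik == pytest.approx(glm.llf)

    def test_fit_is_local_maximum(self, rng):
        from burnoutnet.ergm import _collapsed_loglik

        attrs = _attrs(80, 25)
        g = simulate_network([-1.2, -0.2, 0.4], attrs, burnout_spec(),
                             seed=5)
        design = dyad_pattern_design(g, burnout_spec())
        fit = fit_exact(g, burnout_spec())
        best = _collapsed_loglik(fit.coefficients, design)
        for _ in range(25):
            perturbed = fit.coefficients + rng.normal(scale=0.05, size=3)
            assert _collapsed_loglik(perturbed, design) <= best + 1e-12

    def test_separation_reported_not_silent(self):
        # every high-high dyad tied, so that pattern's density is 1
        g = _graph(8, 3, [(0, 1), (0, 2), (1, 2), (3, 4)])
        fit = fit_exact(g, burnout_spec())
        assert not fit.converged
        assert "separation" in fit.message

    def test_information_criteria_identities(self):
        g = _graph(30, 10, [(i, (i + 7) % 30) for i in range(30)])
        for spec in (zero_spec(), burnout_spec()):
            fit = fit_exact(g, spec)
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
            assert fit.bic == pytest.approx(
                fit.k * math.log(30 * 29 / 2) - 2 * fit.loglik)

    def test_sign_recovery_of_homophily(self):
        """theta3 = +/-0.5 at N=500: the fitted nodematch sign matches the
        generating sign in >= 95% of replicates."""
        attrs = _attrs(500, 63)
        for truth in (0.5, -0.5):
            hits = 0
            for rep in range(40):
                g = simulate_network([-4.15, -0.14, truth], attrs,
                                     burnout_spec(), seed=1000 + rep)
                fit = fit_exact(g, burnout_spec())
                if fit.converged and np.sign(
                        fit.coefficient("nodematch.burnout")) == np.sign(
                            truth):
                    hits += 1
            assert hits >= 0.95 * 40 - 2  # binomial slack at 40 reps


class TestSimulate:
    def test_huge_negative_edges_theta_gives_empty_graph(self):
        g = simulate_network([-50.0, 0.0, 0.0], _attrs(40, 10),
                             burnout_spec(), seed=1)
        assert g.number_of_edges() == 0

    def test_zero_theta_density_half(self):
        g = simulate_network([0.0], {f"n{i}": "low" for i in range(60)},
                             zero_spec(), seed=2)
        d = 60 * 59 / 2
        assert abs(g.number_of_edges() - d / 2) < 4 * np.sqrt(d * 0.25)

    def test_fixed_seed_identical_graphs(self):
        a = simulate_network([-1.0, 0.2, 0.3], _attrs(30, 8),
                             burnout_spec(), seed=9)
        b = simulate_network([-1.0, 0.2, 0.3], _attrs(30, 8),
                             burnout_spec(), seed=9)
        assert set(a.edges) == set(b.edges)


class TestMhSampler:
    def test_zero_theta_stationary_edge_count(self):
        g0 = nx.empty_graph(12)
        for i in g0.nodes:
            g0.nodes[i]["burnout"] = "low"
        stats = mh_sampler(g0, [0.0], zero_spec(),
                           ErgmControl(seed=4, n_samples=400))
        d = 66
        se = np.sqrt(d * 0.25 / 400) * 3  # ignores autocorrelation: loose
        assert abs(stats[:, 0].mean() - d / 2) < 6 * se

    def test_sampled_means_match_analytic_expectations(self):
        """E[g] = sum_patterns n_dyads * sigmoid(theta . delta) under dyad
        independence."""
        theta = np.array([-0.8, -0.3, 0.5])
        g0 = _graph(14, 5, [])
        design = dyad_pattern_design(g0, burnout_spec())
        expected = design.deltas.T @ (
            design.n_dyads * expit(design.deltas @ theta))
        for sampler in ("blocked", "sequential"):
            stats = mh_sampler(g0, theta, burnout_spec(),
                               ErgmControl(seed=8, n_samples=600,
                                           sampler=sampler))
            err = np.abs(stats.mean(axis=0) - expected)
            sd = stats.std(axis=0) / np.sqrt(600)
            assert np.all(err < 8 * sd + 0.5), (sampler, err)

    def test_zero_score_toggle_always_accepted(self):
        """With theta=0 every proposal has score 0 and acceptance 1: on a
        single dyad the sequential chain alternates deterministically."""
        g0 = nx.Graph()
        g0.add_nodes_from([0, 1])
        stats = mh_sampler(g0, [0.0], zero_spec(),
                           ErgmControl(seed=0, burn_in=0, interval=1,
                                       n_samples=6, sampler="sequential"))
        assert stats[:, 0].tolist() == [1, 0, 1, 0, 1, 0]

    def test_blocked_and_sequential_same_law(self):
        theta = np.array([-0.5])
        g0 = nx.empty_graph(10)
        a = mh_sampler(g0, theta, zero_spec(),
                       ErgmControl(seed=3, n_samples=500))
        b = mh_sampler(g0, theta, zero_spec(),
                       ErgmControl(seed=3, n_samples=500,
                                   sampler="sequential"))
        pooled_sd = np.sqrt(a[:, 0].var() / 500 + b[:, 0].var() / 500)
        assert abs(a[:, 0].mean() - b[:, 0].mean()) < 5 * pooled_sd


class TestMcmcMle:
    def test_zero_iterations_returns_initializer(self):
        attrs = _attrs(60, 18)
        g = simulate_network([-1.5, -0.2, 0.4], attrs, burnout_spec(),
                             seed=3)
        exact = fit_exact(g, burnout_spec())
        fit = fit_mcmcmle(g, burnout_spec(), ErgmControl(seed=1, max_iter=0))
        assert np.allclose(fit.coefficients, exact.coefficients)
        assert fit.method == "mcmc_mle"

    def test_fixed_seed_identical_fit(self):
        attrs = _attrs(40, 12)
        g = simulate_network([-1.0, -0.2, 0.4], attrs, burnout_spec(),
                             seed=6)
        control = ErgmControl(seed=11, n_samples=300, max_iter=3)
        a = fit_mcmcmle(g, burnout_spec(), control)
        b = fit_mcmcmle(g, burnout_spec(), control)
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_agrees_with_exact_fit(self):
        attrs = _attrs(100, 30)
        g = simulate_network([-1.8, -0.3, 0.5], attrs, burnout_spec(),
                             seed=21)
        exact = fit_exact(g, burnout_spec())
        fit = fit_mcmcmle(g, burnout_spec(),
                          ErgmControl(seed=2, n_samples=800, max_iter=8))
        assert np.max(np.abs(fit.coefficients - exact.coefficients)) < 0.05


class TestComparisonAndPrediction:
    def test_homophilous_network_selects_attribute_model(self):
        attrs = _attrs(300, 60)
        g = simulate_network([-2.5, -0.1, 0.5], attrs, burnout_spec(),
                             seed=31)
        comparison = compare_models(fit_exact(g, zero_spec()),
                                    fit_exact(g, burnout_spec()))
        assert comparison.selected == "node_attribute"

    def test_null_network_selects_zero_model_by_bic(self):
        attrs = _attrs(300, 60)
        wins = 0
        reps = 10
        for rep in range(reps):
            g = simulate_network([-2.5], {k: None for k in attrs},
                                 zero_spec(), seed=rep)
            for node, status in attrs.items():
                g.nodes[node]["burnout"] = status
            comparison = compare_models(fit_exact(g, zero_spec()),
                                        fit_exact(g, burnout_spec()))
            if comparison.selected == "zero":
                wins += 1
        assert wins >= reps // 2 + 1

    def test_identical_fits_flag_tie(self):
        g = _graph(20, 6, [(i, (i + 1) % 20) for i in range(20)])
        fit = fit_exact(g, zero_spec())
        comparison = compare_models(fit, fit)
        assert comparison.tie

    def test_different_networks_rejected(self):
        g1 = _graph(10, 3, [(0, 1)])
        g2 = _graph(10, 3, [(0, 2)])
        with pytest.raises(ErgmError, match="different networks"):
            compare_models(fit_exact(g1, zero_spec()),
                           fit_exact(g2, zero_spec()))

    def test_published_theta_low_low_probability(self):
        """theta=(-4.65, -0.14, 0.09): a low-low dyad ties with probability
        logistic(-4.56) ~ 0.01036."""
        g = _graph(10, 3, [(0, 1), (3, 4)])
        fit = fit_exact(g, burnout_spec())
        fit.coefficients = np.array([-4.65, -0.14, 0.09])
        p = predicted_edge_probability(fit, "low", "low")
        assert p == pytest.approx(expit(-4.56), abs=1e-6)
        assert p == pytest.approx(0.01036, abs=5e-5)

    def test_zero_theta_probability_half_everywhere(self):
        g = _graph(10, 3, [(0, 1)])
        fit = fit_exact(g, burnout_spec())
        fit.coefficients = np.zeros(3)
        for pair in (("low", "low"), ("low", "high"), ("high", "high")):
            assert predicted_edge_probability(fit, *pair) == 0.5

    def test_hh_exceeds_lh_iff_factor_plus_match_positive(self, rng):
        g = _graph(10, 3, [(0, 1)])
        fit = fit_exact(g, burnout_spec())
        for _ in range(50):
            theta = rng.normal(scale=1.0, size=3)
            fit.coefficients = theta
            hh = predicted_edge_probability(fit, "high", "high")
            lh = predicted_edge_probability(fit, "low", "high")
            assert (hh > lh) == (theta[1] + theta[2] > 0)


def test_spec_validation():
    with pytest.raises(ErgmError):
        ErgmTerm("triangles")
    with pytest.raises(ErgmError):
        ErgmTerm("nodematch")
    with pytest.raises(ErgmError):
        ErgmSpec(())
    with pytest.raises(ErgmError):
        ErgmSpec((ErgmTerm("edges"), ErgmTerm("edges")))
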