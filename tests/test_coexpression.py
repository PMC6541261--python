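"""Correlation networks, threshold selection, and power-law validation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import zeta

from coreseq._util import ParameterError
from coreseq.coexpression import (
    Network,
    ThresholdCriteria,
    REPORT_COLUMNS,
    default_grid,
    degree_loglog_fit,
    network_at_threshold,
    powerlaw_bootstrap,
    powerlaw_mle,
    select_threshold,
    smallworld_stats,
    spearman_matrix,
)
from coreseq.simulate import simulate_coexpression, simulate_powerlaw_degrees

MODULE_SIZES = [2] * 50 + [3] * 12 + [4] * 5 + [5] * 3 + [7] * 2 + [9]


class TestSpearman:
    def test_monotone_relation_gives_rho_one(self):
        expr = pd.DataFrame([[1, 2, 3, 4], [2, 4, 9, 100]], index=["a", "b"],
                            columns=list("wxyz"))
        assert spearman_matrix(expr).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_rank_example(self):
        expr = pd.DataFrame([[1, 2, 3, 4], [1, 3, 2, 4]], index=["a", "b"],
                            columns=list("wxyz"))
        assert spearman_matrix(expr).loc["a", "b"] == pytest.approx(0.8)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(20, 10)))
        got = spearman_matrix(expr).to_numpy()
        want, _ = stats.spearmanr(expr.to_numpy(), axis=1)
        assert np.allclose(got, want, atol=1e-12)

    def test_constant_gene_zeroed(self):
        expr = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "b"],
                            columns=list("wxyz"))
        m = spearman_matrix(expr)
        assert m.loc["flat", "b"] == 0.0 and m.loc["flat", "flat"] == 1.0


class TestNetwork:
    def test_planted_clique_at_threshold(self):
        expr, truth = simulate_coexpression(1, [5], within_r=0.99, n_background=0,
                                            n_samples=60, seed=1)
        net = network_at_threshold(spearman_matrix(expr), 0.9)
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 10

    def test_edge_count_matches_upper_triangle_scan(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(30, 12)))
        corr = spearman_matrix(expr)
        tau = 0.5
        net = network_at_threshold(corr, tau)
        M = corr.to_numpy()
        expected = sum(
            abs(M[i, j]) >= tau
            for i in range(30) for j in range(i + 1, 30))
        assert net.graph.number_of_edges() == expected

    def test_isolated_genes_excluded_and_monotone_shrinkage(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(25, 12)))
        corr = spearman_matrix(expr)
        lo = network_at_threshold(corr, 0.4)
        hi = network_at_threshold(corr, 0.6)
        assert {frozenset(e) for e in hi.graph.edges} <= {
            frozenset(e) for e in lo.graph.edges}
        for n in lo.graph.nodes:
            assert lo.graph.degree(n) >= 1


class TestDegreeFit:
    def test_exact_power_law_recovers_slope_and_r2(self):
        # frequencies exactly proportional to k^-2 over k = 1..50
        k = np.arange(1, 51)
        counts = np.round(1e6 * k**-2.0).astype(int)
        degrees = np.repeat(k, counts)
        a, _c, r2 = degree_loglog_fit(degrees)
        assert a == pytest.approx(2.0, abs=0.01)
        assert r2 > 0.9999

    def test_regular_graph_is_an_error(self):
        with pytest.raises(ParameterError, match="distinct"):
            degree_loglog_fit(np.full(10, 4))

    def test_preferential_attachment_graph_looks_scale_free(self):
        g = nx.barabasi_albert_graph(3000, 2, seed=0)
        degs = np.array([d for _, d in g.degree()])
        a, _c, r2 = degree_loglog_fit(degs)
        assert 1.0 < a < 3.0
        assert r2 >= 0.8


class TestSmallWorld:
    def test_complete_graph(self):
        net = Network(graph=nx.complete_graph(4), threshold=0.9)
        sw = smallworld_stats(net)
        assert sw.mean_cc == pytest.approx(1.0)
        assert sw.mean_path == pytest.approx(1.0)

    def test_path_graph_mean_path(self):
        net = Network(graph=nx.path_graph(4), threshold=0.9)
        sw = smallworld_stats(net)
        assert sw.mean_path == pytest.approx(10 / 6)
        assert sw.mean_cc == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        # triangle counting and BFS by hand on 100 random graphs <= 30 nodes
        rng = np.random.default_rng(4)
        for trial in range(100):
            n = int(rng.integers(4, 31))
            p = float(rng.uniform(0.1, 0.6))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            sw = smallworld_stats(Network(graph=g, threshold=0.5))
            # brute-force clustering
            ccs = []
            for v in g.nodes:
                nbrs = list(g.neighbors(v))
                k = len(nbrs)
                if k < 2:
                    ccs.append(0.0)
                    continue
                links = sum(g.has_edge(a, b) for i, a in enumerate(nbrs)
                            for b in nbrs[i + 1:])
                ccs.append(2 * links / (k * (k - 1)))
            assert sw.mean_cc == pytest.approx(np.mean(ccs), abs=1e-12)
            # brute-force BFS mean path on the largest component
            comp = max(nx.connected_components(g), key=len)
            dists = []
            for src in comp:
                seen = {src: 0}
                frontier = [src]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in g.neighbors(u):
                            if v in comp and v not in seen:
                                seen[v] = seen[u] + 1
                                nxt.append(v)
                    frontier = nxt
                dists.extend(d for v, d in seen.items() if v != src)
            if dists:
                assert sw.mean_path == pytest.approx(np.mean(dists), abs=1e-12)


class TestThresholdSelection:
    def test_default_grid_contains_reported_threshold(self):
        grid = default_grid()
        assert np.any(np.isclose(grid, 0.914))

    def test_planted_modules_pass_below_within_r(self):
        expr, truth = simulate_coexpression(
            len(MODULE_SIZES), MODULE_SIZES, within_r=0.92, n_background=60,
            n_samples=120, seed=0)
        corr = spearman_matrix(expr)
        tau, report = select_threshold(corr)
        assert tau is not None and tau <= 0.92
        net = network_at_threshold(corr, tau)
        for a, b in truth.network_edges:
            assert net.graph.has_edge(a, b)
        assert list(report.table.columns) == REPORT_COLUMNS

    def test_pure_noise_yields_explicit_no_pass(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(120, 23)))
        tau, report = select_threshold(spearman_matrix(expr))
        assert tau is None
        assert "no threshold" in report.status
        assert not report.table.passed.any()

    def test_highest_preference_configurable(self):
        expr, _ = simulate_coexpression(
            len(MODULE_SIZES), MODULE_SIZES, within_r=0.92, n_background=40,
            n_samples=120, seed=2)
        corr = spearman_matrix(expr)
        lo, _ = select_threshold(corr)
        hi, _ = select_threshold(corr, criteria=ThresholdCriteria(prefer="highest"))
        assert lo is not None and hi is not None and hi >= lo


class TestPowerLawMLE:
    def test_continuous_limit_against_likelihood_grid(self):
        # {2,4,8,16} with xmin=2: continuous MLE is 1 + 4/(6 ln 2) ~ 1.962;
        # the discrete MLE must agree with a brute-force likelihood grid
        sample = np.array([2, 4, 8, 16])
        fit = powerlaw_mle(sample, xmin=2)
        grid = np.linspace(1.05, 5.0, 4000)
        ll = [-len(sample) * np.log(zeta(a, 2)) - a * np.log(sample).sum()
              for a in grid]
        assert fit.alpha == pytest.approx(grid[int(np.argmax(ll))], abs=2e-3)

    def test_alpha_recovery_large_sample(self):
        x = simulate_powerlaw_degrees(2.5, 1, 100_000, seed=6)
        fit = powerlaw_mle(x)
        assert fit.alpha == pytest.approx(2.5, abs=0.05)

    def test_xmin_at_minimum_keeps_whole_sample(self):
        x = simulate_powerlaw_degrees(2.0, 3, 500, seed=7)
        fit = powerlaw_mle(x, xmin=int(x.min()))
        assert fit.n_tail == len(x)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            powerlaw_mle(np.array([1, 2, 3]))


class TestPowerLawBootstrap:
    def test_fixed_seed_reproduces_p_value(self):
        x = simulate_powerlaw_degrees(2.5, 1, 1500, seed=8)
        f1 = powerlaw_bootstrap(x, n_boot=100, seed=9)
        f2 = powerlaw_bootstrap(x, n_boot=100, seed=9)
        assert f1.p_value == f2.p_value
        assert f1.alpha_ci is not None and f1.alpha_ci[0] <= f1.alpha_ci[1]

    def test_exponential_tail_rejected(self):
        rng = np.random.default_rng(10)
        geom = rng.geometric(0.05, size=10_000)
        fit = powerlaw_bootstrap(geom, n_boot=100, seed=11)
        assert fit.p_value < 0.1

    def test_self_simulated_data_rarely_rejected(self):
        # the GOF p-value is roughly uniform under the null, so rejections at
        # 0.1 should stay near the nominal rate across independent runs
        ps = []
        for i in range(10):
            x = simulate_powerlaw_degrees(2.5, 2, 1000, seed=500 + i)
            ps.append(powerlaw_bootstrap(x, n_boot=100, seed=600 + i).p_value)
        assert sum(p >= 0.1 for p in ps) >= 7
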