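"""Variational PLN fitting, the penalty path, partial correlations,
network thresholding, and StARS selection."""

import numpy as np
import pytest

import rhizonet as rz
from rhizonet.pln import (
    PartialCorrelationMatrix, fit_pln, model_r2, null_loglik,
    partial_correlation, penalty_grid, precision_path, saturated_loglik,
    threshold_network, ModelCriteria,
)
from rhizonet.simulate import build_precision, simulate_pln_counts
from rhizonet.stars import StarsConfig, stars_select, subsample_size, total_instability

from conftest import make_table


def elbo_is_monotone(trace, rel=1e-6):
    t = np.asarray(trace)
    return np.all(np.diff(t) >= -rel * (np.abs(t[:-1]) + 1.0))


@pytest.fixture(scope="module")
def planted_table():
    theta, _ = build_precision(12, {(0, 1), (2, 3), (4, 5)}, 0.4)
    table, _ = simulate_pln_counts(theta, 3.0, 80, seed=5)
    return table, theta


class TestFitPln:
    def test_single_otu_degenerate_dimension(self):
        # explicit zero offsets: with a single OTU, total-count offsets make
        # the intercept-only model saturated and the fit rightly refuses
        table = make_table([[3, 9, 1, 5, 2, 8]])
        with pytest.raises(ValueError, match="degenerate"):
            fit_pln(table, penalty=0.7)
        fit = fit_pln(table, offsets=np.zeros(6), penalty=0.7)
        assert fit.precision.theta.shape == (1, 1)
        assert fit.precision.support == set()
        assert elbo_is_monotone(fit.elbo_trace)

    def test_elbo_monotone_with_and_without_penalty(self, planted_table):
        table, _ = planted_table
        for pen in (0.0, 0.2):
            fit = fit_pln(table, penalty=pen)
            assert elbo_is_monotone(fit.elbo_trace)

    def test_saturated_limit_latent_means(self):
        # all counts large: the Poisson layer pins Z at log(count) - offset
        # (unit latent variance, mean high enough that every draw is >= 1000)
        theta = np.eye(3)
        table, offsets = simulate_pln_counts(theta, 10.0, 20,
                                             depth_log_sd=0.1, seed=2)
        assert table.counts.min() >= 1000
        fit = fit_pln(table, offsets=offsets, penalty=0.0)
        expect = np.log(table.counts.T) - offsets[:, None]
        assert np.max(np.abs(fit.latent_means - expect)) < 0.05

    def test_sigma_theta_inverse_consistency(self, planted_table):
        table, _ = planted_table
        fit = fit_pln(table, penalty=0.2)
        prod = fit.precision.sigma @ fit.precision.theta
        assert np.allclose(prod, np.eye(table.n_otus), atol=1e-6)

    def test_offset_shift_leaves_support_unchanged(self, planted_table):
        # a global depth rescaling enters only through the offsets
        table, _ = planted_table
        o = rz.default_offsets(table)
        f1 = fit_pln(table, offsets=o, penalty=0.25)
        f2 = fit_pln(table, offsets=o + np.log(3.0), penalty=0.25)
        assert f1.precision.support == f2.precision.support
        assert np.allclose(f1.precision.theta, f2.precision.theta, atol=1e-2)

    def test_negative_penalty_rejected(self, planted_table):
        with pytest.raises(ValueError):
            fit_pln(planted_table[0], penalty=-0.1)


class TestPrecisionPath:
    def test_path_endpoints_and_r2_monotone(self, planted_table):
        table, _ = planted_table
        init = fit_pln(table, penalty=1e6, on_nonconvergence="warn")
        grid = penalty_grid(init.latent_covariance, 6)
        fits = precision_path(table, penalties=grid)
        assert len(fits[0].precision.support) == 0  # empty at the sparse end
        sizes = [len(f.precision.support) for f in fits]
        assert sizes[-1] > sizes[0]
        r2 = [f.criteria.pseudo_r2 for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(r2, r2[1:]))

    def test_zero_penalty_dense_support(self):
        theta, _ = build_precision(4, set(), 0.3)
        table, _ = simulate_pln_counts(theta, 3.0, 60, seed=8)
        fits = precision_path(table, penalties=np.array([0.5, 0.0]))
        assert len(fits[-1].precision.support) == 6  # all pairs allowed

    def test_increasing_grid_rejected(self, planted_table):
        with pytest.raises(ValueError):
            precision_path(planted_table[0], penalties=np.array([0.1, 0.2]))


class TestModelCriteria:
    def test_r2_zero_at_null_and_one_at_saturated(self):
        from rhizonet.pln import _criteria, SparsePrecision

        y = np.array([[3.0, 10.0], [5.0, 2.0], [7.0, 1.0]])
        o = np.zeros(3)
        prec = SparsePrecision(["a", "b"], np.eye(2), np.eye(2), 0.0)
        at_null = _criteria(y, o, null_loglik(y, o), prec)
        assert at_null.pseudo_r2 == pytest.approx(0.0, abs=1e-12)
        at_sat = _criteria(y, o, saturated_loglik(y), prec)
        assert at_sat.pseudo_r2 == pytest.approx(1.0, abs=1e-12)

    def test_model_r2_picks_bic_best(self):
        path = [ModelCriteria(-10, -20, 0.3, 5),
                ModelCriteria(-8, -15, 0.6, 9),
                ModelCriteria(-7, -18, 0.9, 20)]
        assert model_r2(path) == 0.6


class TestPartialCorrelation:
    def test_diagonal_theta_gives_zero(self):
        pc = partial_correlation(np.diag([2.0, 3.0, 4.0]))
        off = pc.r - np.diag(np.diag(pc.r))
        assert np.allclose(off, 0)

    def test_two_by_two_closed_form(self):
        pc = partial_correlation(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert pc.r[0, 1] == pytest.approx(0.5)

    def test_sign_rule(self):
        pc = partial_correlation(np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert pc.r[0, 1] < 0  # positive precision entry -> negative r

    def test_matches_conditioning_oracle(self, rng):
        # independent route: Schur-complement conditioning on the covariance
        from test_simulate import conditional_parcor

        for _ in range(5):
            theta, _ = build_precision(
                8, {(0, 1), (2, 5), (3, 4, -1)}, float(rng.uniform(0.2, 0.45)))
            sigma = np.linalg.inv(theta)
            pc = partial_correlation(theta)
            for j in range(8):
                for k in range(j + 1, 8):
                    assert pc.r[j, k] == pytest.approx(
                        conditional_parcor(sigma, j, k), abs=1e-8)

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestThresholdNetwork:
    def _parcor(self, r01, r02=0.0):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        r[0, 2] = r[2, 0] = r02
        return PartialCorrelationMatrix(["a", "b", "c"], r)

    def test_threshold_is_strict(self):
        pc = self._parcor(0.05, 0.07)
        net = threshold_network(pc, min_abs_r=0.06)
        assert net.edge_pairs() == {("a", "c")}

    def test_zero_threshold_keeps_all_nonzero(self):
        pc = self._parcor(0.5, -0.2)
        net = threshold_network(pc, min_abs_r=0.0)
        assert net.n_edges == 2
        assert net.sign(("a", "c")) == -1

    def test_all_below_threshold_empty(self):
        net = threshold_network(self._parcor(0.01), min_abs_r=0.06)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_stability_filter(self):
        pc = self._parcor(0.5, 0.5)
        freq = {("a", "b"): 1.0, ("a", "c"): 0.4}
        net = threshold_network(pc, 0.06, stability=freq, min_frequency=0.9)
        assert net.edge_pairs() == {("a", "b")}
        assert net.stability[("a", "b")] == 1.0


class TestStars:
    def test_default_config_echoes_thirty_subsamples(self):
        assert StarsConfig().n_subsamples == 30

    def test_subsample_size_rule(self):
        assert subsample_size(70) == 56          # 0.8 n cap binds
        assert subsample_size(400) == 200        # floor(10 sqrt(n))
        with pytest.raises(ValueError):
            subsample_size(3, requested=2)

    def test_bernoulli_half_frequencies_give_half_instability(self, rng):
        # binomial oracle: f ~ Bin(30, 0.5)/30 -> E[2f(1-f)] = 0.5 - var term
        f = rng.binomial(30, 0.5, size=20000) / 30
        expect = 2 * 0.25 - 2 * 0.25 / 30
        assert total_instability(f) == pytest.approx(expect, abs=0.01)

    def test_identical_subsamples_select_densest_penalty(self):
        theta, _ = build_precision(6, {(0, 1)}, 0.4)
        table, _ = simulate_pln_counts(theta, 3.0, 30, seed=4)
        cfg = StarsConfig(n_subsamples=5, subsample_size=30, seed=0)
        res, _ = stars_select(table, config=cfg, n_penalties=5)
        assert np.allclose(res.instability[~np.isnan(res.instability)], 0.0)
        assert res.selected_index == len(res.penalties) - 1

    def test_early_stop_matches_full_scan(self):
        theta, _ = build_precision(10, {(0, 1), (2, 3)}, 0.4)
        table, _ = simulate_pln_counts(theta, 3.0, 50, seed=6)
        full = fit_pln(table, penalty=1e6, on_nonconvergence="warn")
        res_fast, _ = stars_select(
            table, config=StarsConfig(seed=3, early_stop=True),
            full_fit=full, n_penalties=8)
        res_slow, _ = stars_select(
            table, config=StarsConfig(seed=3, early_stop=False),
            full_fit=full, n_penalties=8)
        assert res_fast.selected_penalty == res_slow.selected_penalty
        assert res_fast.frequencies == res_slow.frequencies

    def test_diagonal_truth_selects_empty_network(self):
        # planted independence: the selected model should carry no edges
        # in nearly all seeded replicates
        empty = 0
        runs = 20
        for seed in range(runs):
            theta = np.eye(8)
            table, _ = simulate_pln_counts(theta, 3.0, 50, seed=100 + seed)
            res, fit = stars_select(
                table, config=StarsConfig(seed=seed), n_penalties=6)
            net = threshold_network(partial_correlation(fit.precision),
                                    min_abs_r=0.06,
                                    stability=res.frequencies,
                                    min_frequency=0.9)
            if net.n_edges == 0:
                empty += 1
        assert empty >= int(0.95 * runs)
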