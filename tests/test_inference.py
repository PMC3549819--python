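import numpy as np
import pytest

from rareprob import (
    BetaHyper,
    GenotypeMatrix,
    HiddenStates,
    MRFParams,
    Phenotypes,
    PriorScores,
    RunConfig,
    SimConfig,
    TransitionState,
    association_test,
    build_neighborhood,
    carrier_counts,
    converged,
    estimate_beta_hyper,
    fit_mrf_params,
    icm_update_states,
    init_states,
    run_rareprob,
    sim_fixed,
)
from rareprob.hmrf_model import emission_loglik_causal, emission_loglik_null, field_prob_X
from rareprob.inference import _pl_objective_R, _pl_objective_X
from rareprob.site_stats import SiteStats


def _stats(c_plus, c_minus, n_case, n_ctrl):
    c_plus = np.asarray(c_plus)
    c_minus = np.asarray(c_minus)
    from rareprob.site_stats import z_statistic

    return SiteStats(
        c_plus=c_plus,
        c_minus=c_minus,
        n_case=n_case,
        n_ctrl=n_ctrl,
        theta_hat=c_plus / n_case,
        rho_hat=c_minus / n_ctrl,
        z=np.atleast_1d(z_statistic(c_plus, c_minus, n_case, n_ctrl)),
    )


class TestInitStates:
    def test_all_zero_statistics(self):
        s = _stats([0, 0, 0], [0, 0, 0], 10, 10)
        st = init_states(s)
        assert st.X.tolist() == [0, 0, 0]
        assert st.R.tolist() == [0, 0, 0]

    def test_priors_override_statistics(self):
        s = _stats([9, 0, 0], [0, 0, 0], 10, 10)
        st = init_states(s, priors=PriorScores(causal_hint=np.array([1.0, 0.0, 0.0])))
        assert st.X.tolist() == [1, 0, 0]

    def test_region_seed_covers_clustered_flags(self):
        z = np.array([3.0] * 5 + [0.0] * 5)
        s = _stats(np.zeros(10), np.zeros(10), 10, 10)
        s.z = z
        st = init_states(s, z_init=1.0, region_window=4)
        assert st.X.tolist() == [1] * 5 + [0] * 5
        # windowed mean (zero padded) reaches 0.5 through the run and just past it
        assert st.R.tolist() == [1] * 6 + [0] * 4


class TestEstimateBetaHyper:
    def test_method_of_moments_example(self):
        a = np.sqrt(0.05)
        alpha, beta = estimate_beta_hyper([0.5 - a, 0.5 + a])
        assert (alpha, beta) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_constant_values_fall_back_flat(self):
        assert estimate_beta_hyper([0.3, 0.3, 0.3]) == (1.0, 1.0)

    def test_single_value_falls_back_flat(self):
        assert estimate_beta_hyper([0.4]) == (1.0, 1.0)

    def test_empty_falls_back_flat(self):
        assert estimate_beta_hyper([]) == (1.0, 1.0)

    def test_sampling_noise_correction(self, rng):
        # proportions c/n from a single shared rate: the observed spread is
        # pure binomial noise, so the corrected fit must go flat
        n = 500
        props = rng.binomial(n, 0.01, size=200) / n
        assert estimate_beta_hyper(props, sizes=n) == (1.0, 1.0)
        # while a genuinely dispersed rate distribution keeps an informative fit
        rates = rng.beta(2, 200, size=200)
        props = rng.binomial(n, rates) / n
        alpha, beta = estimate_beta_hyper(props, sizes=n)
        assert (alpha, beta) != (1.0, 1.0)


class TestFitMrfParams:
    def test_all_zero_states_convention(self):
        W = build_neighborhood(np.array([1.0, -1.0, 0.5]))
        params = fit_mrf_params(
            HiddenStates(np.zeros(3, dtype=int), np.array([1, 0, 0])),
            W,
            TransitionState(xi=0.6, zeta=0.2),
        )
        assert params.gamma == 0.0

    def test_maximization_beats_dense_grid(self, rng):
        m = 5
        W = build_neighborhood(rng.normal(size=m))
        X = np.array([1, 0, 1, 1, 0])
        R = np.array([1, 1, 0, 1, 0])
        states = HiddenStates(X, R)
        trans = TransitionState(xi=0.7, zeta=0.2)
        params = fit_mrf_params(states, W, trans, region_halfwidth=2)

        q = np.where(R == 1, trans.xi, trans.zeta)
        logit_q = np.log(q) - np.log(1 - q)
        grid_best = max(
            _pl_objective_X(g, X.astype(float), logit_q) for g in np.linspace(0, 5, 501)
        )
        assert _pl_objective_X(params.gamma, X.astype(float), logit_q) >= grid_best - 1e-6

        from rareprob.hmrf_model import region_neighbor_sum

        t = region_neighbor_sum(R, 2)
        grid_best_r = max(
            _pl_objective_R(tau, ups, R.astype(float), t)
            for tau in np.linspace(-3, 3, 61)
            for ups in np.linspace(0.05, 3, 60)
        )
        assert _pl_objective_R(params.tau, params.upsilon, R.astype(float), t) >= (
            grid_best_r - 1e-3
        )

    def test_objective_not_below_incoming(self, rng):
        W = build_neighborhood(rng.normal(size=4))
        states = HiddenStates(np.array([1, 0, 0, 1]), np.array([1, 1, 0, 0]))
        trans = TransitionState(xi=0.5, zeta=0.1)
        incoming = MRFParams(gamma=2.0, eta=1.0, tau=-1.0, upsilon=0.3)
        params = fit_mrf_params(states, W, trans, current=incoming)
        q = np.where(states.R == 1, trans.xi, trans.zeta)
        logit_q = np.log(q) - np.log(1 - q)
        assert _pl_objective_X(params.gamma, states.X.astype(float), logit_q) >= (
            _pl_objective_X(incoming.gamma, states.X.astype(float), logit_q) - 1e-9
        )


class TestIcmUpdate:
    def test_overwhelming_causal_emission_selects_site(self):
        stats = _stats([50, 1], [0, 1], 1000, 1000)
        W = build_neighborhood(stats.z)
        states = HiddenStates(np.array([0, 0]), np.array([0, 0]))
        hyper = BetaHyper(alpha_theta=0.5, beta_theta=50, alpha_rho=0.5, beta_rho=50,
                          alpha_null=0.5, beta_null=50)
        new = icm_update_states(
            stats, states, MRFParams(gamma=1.0), TransitionState(xi=0.5, zeta=0.5),
            hyper, W,
        )
        assert new.X[0] == 1

    def test_exact_tie_keeps_previous_state(self, monkeypatch):
        # force an exact emission tie so both causal states score equally;
        # with xi = zeta the region rate carries no contrast either
        import rareprob.inference as inf

        monkeypatch.setattr(inf, "emission_loglik_causal",
                            lambda *a, **k: np.zeros(2))
        monkeypatch.setattr(inf, "emission_loglik_null",
                            lambda *a, **k: np.zeros(2))
        stats = _stats([0, 0], [0, 0], 2, 2)
        W = build_neighborhood(np.array([0.1, -0.1]))
        states = HiddenStates(np.array([1, 0]), np.array([1, 0]))
        new = icm_update_states(
            stats, states, MRFParams(gamma=1.0, tau=0.0, upsilon=0.5),
            TransitionState(xi=0.5, zeta=0.5), BetaHyper(), W, region_halfwidth=0,
        )
        assert new.X.tolist() == [1, 0]
        assert new.R.tolist() == [1, 0]

    def test_repeated_sweeps_reach_fixed_point(self, rng):
        data = sim_fixed(SimConfig(m=20, k=5, n=200, delta=0.2, seed=3))
        stats = carrier_counts(data.genotypes, data.phenotypes)
        W = build_neighborhood(stats.z)
        states = HiddenStates(rng.integers(0, 2, 20), rng.integers(0, 2, 20))
        params = MRFParams(gamma=1.0, eta=1.0, tau=-0.5, upsilon=0.8)
        trans = TransitionState(xi=0.6, zeta=0.1)
        hyper = BetaHyper()
        for _ in range(60):
            new = icm_update_states(stats, states, params, trans, hyper, W)
            if np.array_equal(new.X, states.X) and np.array_equal(new.R, states.R):
                break
            states = new
        again = icm_update_states(stats, states, params, trans, hyper, W)
        assert np.array_equal(again.X, states.X)
        assert np.array_equal(again.R, states.R)

    def test_sweep_is_monotone_in_causal_objective(self, rng):
        """With parameters frozen, one sweep cannot decrease the causal-state
        objective sum(emission + log field probability)."""
        for seed in range(5):
            data = sim_fixed(SimConfig(m=20, k=5, n=200, delta=0.2, seed=seed))
            stats = carrier_counts(data.genotypes, data.phenotypes)
            W = build_neighborhood(stats.z)
            states = HiddenStates(rng.integers(0, 2, 20), rng.integers(0, 2, 20))
            params = MRFParams(gamma=float(rng.uniform(0, 2)), tau=float(rng.normal()),
                               upsilon=float(rng.uniform(0.1, 2)))
            trans = TransitionState(xi=float(rng.uniform(0.4, 0.9)),
                                    zeta=float(rng.uniform(0.01, 0.3)))
            hyper = BetaHyper()

            def objective(st):
                e1 = emission_loglik_causal(stats.c_plus, stats.c_minus,
                                            stats.n_case, stats.n_ctrl, hyper)
                e0 = emission_loglik_null(stats.c_plus + stats.c_minus,
                                          stats.n_case + stats.n_ctrl, hyper)
                p1 = np.clip(field_prob_X(states.R, params, trans), 1e-12, 1 - 1e-12)
                x = st.X.astype(float)
                return float(np.sum(x * (e1 + np.log(p1)) + (1 - x) * (e0 + np.log1p(-p1))))

            new = icm_update_states(stats, states, params, trans, hyper, W)
            assert objective(new) >= objective(states) - 1e-9


class TestConverged:
    def test_identical_vectors(self):
        assert converged(np.array([1, 0, 1]), np.array([1, 0, 1]))

    def test_one_flip_not_converged_at_default_tol(self):
        assert not converged(np.array([1, 0]), np.array([0, 0]), tol=1.0)

    def test_two_flips_distance(self):
        assert converged(np.array([1, 0, 1]), np.array([0, 1, 1]), tol=np.sqrt(2) + 1e-9)
        assert not converged(np.array([1, 0, 1]), np.array([0, 1, 1]), tol=np.sqrt(2))


class TestAssociationTest:
    def _collapsible(self, case_carriers, ctrl_carriers, n=1000):
        values = np.zeros((1, 2 * n), dtype=np.int8)
        values[0, :case_carriers] = 1
        values[0, n:n + ctrl_carriers] = 1
        G = GenotypeMatrix(values, ["v0"], [f"s{i}" for i in range(2 * n)])
        P = Phenotypes(np.array([1] * n + [0] * n))
        return G, P

    def test_empty_selection_gives_p_one(self):
        G, P = self._collapsible(100, 50)
        stat, p, sig, risk, prot = association_test(np.array([0]), np.array([3.0]), G, P)
        assert (stat, p, sig) == (0.0, 1.0, False)
        assert risk.size == 0 and prot.size == 0

    def test_collapsed_two_proportion_example(self):
        # 100/1000 case carriers vs 50/1000 controls
        G, P = self._collapsible(100, 50)
        stat, p, sig, risk, _ = association_test(np.array([1]), np.array([3.0]), G, P)
        from scipy.stats import norm

        expected_z = 0.05 / np.sqrt(0.075 * 0.925 * 0.002)
        assert stat == pytest.approx(expected_z)
        assert p == pytest.approx(2 * norm.sf(expected_z))
        assert p == pytest.approx(2.2e-5, rel=0.05)
        assert not sig  # above 2.5e-6

    def test_identical_proportions_give_unit_p(self):
        G, P = self._collapsible(50, 50)
        stat, p, _, _, _ = association_test(np.array([1]), np.array([1.0]), G, P)
        assert stat == 0.0 and p == 1.0

    def test_bonferroni_combination_of_directions(self):
        values = np.zeros((2, 200), dtype=np.int8)
        values[0, :40] = 1  # risk: case carriers
        values[1, 150:190] = 1  # protective: control carriers
        G = GenotypeMatrix(values, ["r", "p"], [f"s{i}" for i in range(200)])
        P = Phenotypes(np.array([1] * 100 + [0] * 100))
        _, p_both, _, risk, prot = association_test(
            np.array([1, 1]), np.array([2.0, -2.0]), G, P
        )
        _, p_risk, _, _, _ = association_test(np.array([1, 0]), np.array([2.0, -2.0]), G, P)
        assert risk.tolist() == [0] and prot.tolist() == [1]
        assert p_both == pytest.approx(min(1.0, 2 * p_risk))


class TestRunRareprob:
    def test_deterministic_given_seed(self):
        data = sim_fixed(SimConfig(m=30, k=10, n=400, delta=0.2, seed=11))
        r1 = run_rareprob(data.genotypes, data.phenotypes, config=RunConfig(seed=5))
        r2 = run_rareprob(data.genotypes, data.phenotypes, config=RunConfig(seed=5))
        assert np.array_equal(r1.X_hat, r2.X_hat)
        assert np.array_equal(r1.R_hat, r2.R_hat)
        assert r1.p_value == r2.p_value
        assert r1.selected_risk == r2.selected_risk

    def test_planted_strong_causal_site_is_selected(self, rng):
        # one site with theta = 0.05 vs rho = 0.001 among 99 null sites
        m, n = 100, 1000
        values = np.zeros((m, 2 * n), dtype=np.int8)
        values[0, :n] = rng.random(n) < 0.05
        values[0, n:] = rng.random(n) < 0.001
        for s in range(1, m):
            values[s] = rng.random(2 * n) < 0.002
        G = GenotypeMatrix(values, [f"v{s}" for s in range(m)], [f"i{j}" for j in range(2 * n)])
        P = Phenotypes(np.array([1] * n + [0] * n))
        result = run_rareprob(G, P)
        assert "v0" in result.selected_risk
        assert result.significant

    def test_result_invariants(self, small_dataset):
        result = run_rareprob(small_dataset.genotypes, small_dataset.phenotypes)
        vid = np.asarray(result.variant_ids)
        selected = set(vid[result.X_hat == 1])
        assert result.selected_risk | result.selected_protective <= selected
        assert result.selected_risk.isdisjoint(result.selected_protective)
        assert 0.0 <= result.p_value <= 1.0
        assert len(result.trace) == result.n_iterations
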