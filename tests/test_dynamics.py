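"""Transition model, likelihood, WAIC, Rhat, AUC, sensitivity threshold."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from rangedyn.dynamics import (
    DynamicsParams,
    TransitionData,
    auc,
    dynamics_loglik,
    factorized_mle,
    fit_dynamics_mcmc,
    rhat,
    sensitivity_threshold,
    transition_probability,
    waic,
)
from rangedyn.dynamics import _waic_chunked

ZERO = DynamicsParams(0, 0, 0, 0, 0, 0)


class TestTransitionProbability:
    def test_all_zero_params_give_half(self):
        for x_prev in (0, 1):
            assert transition_probability(ZERO, x_prev, 0.3, -2.0) == pytest.approx(0.5)

    def test_colonization_at_reference_medians(self, reference_params):
        q = transition_probability(reference_params, 0, 0.0, 0.0)
        assert q == pytest.approx(expit(-1.34), abs=1e-12)
        assert q == pytest.approx(0.2076, abs=5e-4)

    def test_persistence_at_reference_medians(self, reference_params):
        q = transition_probability(reference_params, 1, 1.0, 0.0)
        assert q == pytest.approx(expit(-0.04 + 5.94), abs=1e-12)
        assert q == pytest.approx(0.9973, abs=5e-4)

    @given(
        d=st.floats(min_value=0, max_value=0.99),
        h=st.floats(min_value=-5, max_value=5),
        x_prev=st.sampled_from([0, 1]),
    )
    def test_strictly_increasing_in_d_and_h(self, d, h, x_prev, reference_params):
        q0 = transition_probability(reference_params, x_prev, d, h)
        assert transition_probability(reference_params, x_prev, d + 0.01, h) > q0
        assert transition_probability(reference_params, x_prev, d, h + 0.1) > q0
        assert 0 < q0 < 1


class TestLoglik:
    def test_perfect_prediction_contributes_zero(self):
        params = DynamicsParams(50, 0, 0, 0, 0, 0)  # phi ~ 1
        data = TransitionData(x1978=[1], x2003=[1], d=[0.0], h=[0.0])
        total, per_cell = dynamics_loglik(params, data)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert per_cell.shape == (1,)

    def test_chance_model_closed_form(self):
        data = TransitionData(
            x1978=[0, 1, 0, 1], x2003=[1, 0, 0, 1], d=[0.0] * 4, h=[0.0] * 4
        )
        total, _ = dynamics_loglik(ZERO, data)
        assert total == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_two_cell_hand_computed(self):
        # q = 0.8 for the persisting cell, 0.3 for the empty one
        params = DynamicsParams(
            phi0=float(np.log(0.8 / 0.2)), phi_d=0, phi_h=0,
            gam0=float(np.log(0.3 / 0.7)), gam_d=0, gam_h=0,
        )
        data = TransitionData(x1978=[1, 0], x2003=[1, 0], d=[0.0, 0.0], h=[0.0, 0.0])
        total, _ = dynamics_loglik(params, data)
        assert total == pytest.approx(np.log(0.8) + np.log(0.7), abs=1e-9)


class TestWaic:
    def test_degenerate_point_mass_posterior(self):
        # identical draws with q = 0.5 on two cells: no effective parameters,
        # per-observation generalisation loss = -ln(0.5)
        ll = np.full((10, 2), np.log(0.5))
        w, lppd, p_w = waic(ll)
        assert p_w == pytest.approx(0.0, abs=1e-15)
        assert w == pytest.approx(-np.log(0.5), abs=1e-12)
        assert lppd == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            waic(np.zeros((1, 5)))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_p_waic_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        ll = np.log(rng.uniform(0.01, 1.0, size=(8, 6)))
        _, _, p_w = waic(ll)
        assert p_w >= 0

    def test_chunked_matches_dense(self, rng):
        n = 50
        data = TransitionData(
            x1978=rng.integers(0, 2, n),
            x2003=rng.integers(0, 2, n),
            d=rng.random(n),
            h=rng.normal(size=n),
        )
        draws = rng.normal(scale=0.5, size=(40, 6))
        dense = np.empty((40, n))
        for s in range(40):
            _, dense[s] = dynamics_loglik(DynamicsParams.from_array(draws[s]), data)
        expect = waic(dense)
        got = _waic_chunked(draws, data, chunk=7)
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_generating_model_wins_waic(self, reference_model, reference_params):
        """On data simulated from one dispersal spec, the matching candidate
        attains lower WAIC than a mismatched one in >= 18 of 20 replicates."""
        from rangedyn.grid import NeighborhoodSpec, neighborhood_occupancy
        from rangedyn.habitat import suitability
        from rangedyn.synthetic import LandscapeConfig, generate_landscape, simulate_initial_occupancy, simulate_transition

        grid, env78, env03 = generate_landscape(
            LandscapeConfig(n_rows=45, n_cols=45, seed=21)
        )
        h = suitability(reference_model, env03, grid).h
        true_spec = NeighborhoodSpec(25, 2)
        alt_spec = NeighborhoodSpec(100, 0)
        wins = 0
        for rep in range(20):
            occ78 = simulate_initial_occupancy(
                reference_model, env78, grid, seed=1000 + rep
            )
            d_true = neighborhood_occupancy(occ78, grid, true_spec)
            d_alt = neighborhood_occupancy(occ78, grid, alt_spec)
            occ03 = simulate_transition(
                reference_params, occ78, d_true, h, seed=2000 + rep
            )
            waics = []
            for d in (d_true, d_alt):
                data = TransitionData(occ78.x, occ03.x, d, h)
                fit = fit_dynamics_mcmc(
                    data, chains=2, iterations=300, burnin=100, seed=3000 + rep
                )
                waics.append(fit.waic_per_obs)
            wins += waics[0] < waics[1]
        assert wins >= 18


class TestRhat:
    def test_identical_chains(self):
        x = np.tile(np.random.default_rng(1).normal(size=1000), (3, 1))
        assert rhat(x) <= 1.0 + 1e-9

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert rhat(chains) > 3

    def test_zero_variance_reported_as_one(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert rhat(np.ones((2, 100))) == 1.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_enumerated_pairs(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        scores[labels == 1] += 0.7
        scores[::7] = 0.0  # inject ties
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestSensitivityThreshold:
    def test_twenty_point_ladder(self):
        scores = np.arange(1, 21) * 0.05
        t = sensitivity_threshold(scores, 0.95)
        assert t == pytest.approx(0.10)
        assert np.mean(scores >= t) >= 0.95

    def test_five_scores_keep_all(self):
        t = sensitivity_threshold([0.2, 0.4, 0.6, 0.8, 1.0], 0.95)
        assert t == pytest.approx(0.2)  # need >= 4.75 of 5 above

    def test_full_sensitivity_returns_minimum(self):
        assert sensitivity_threshold([0.3, 0.1, 0.9], 1.0) == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_threshold([], 0.95)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_threshold_always_attains_target(self, scores, target):
        t = sensitivity_threshold(scores, target)
        assert np.mean(np.asarray(scores) >= t) >= target - 1e-12


@pytest.fixture(scope="module")
def small_fit(reference_model, reference_params):
    from rangedyn.grid import NeighborhoodSpec, neighborhood_occupancy
    from rangedyn.habitat import suitability
    from rangedyn.synthetic import LandscapeConfig, generate_landscape, simulate_initial_occupancy, simulate_transition

    grid, env78, env03 = generate_landscape(
        LandscapeConfig(n_rows=55, n_cols=55, seed=8)
    )
    occ78 = simulate_initial_occupancy(reference_model, env78, grid, seed=9)
    spec = NeighborhoodSpec(25, 2)
    d = neighborhood_occupancy(occ78, grid, spec)
    h = suitability(reference_model, env03, grid).h
    occ03 = simulate_transition(reference_params, occ78, d, h, seed=10)
    data = TransitionData(occ78.x, occ03.x, d, h)
    return data, fit_dynamics_mcmc(data, seed=11)


class TestMcmcFit:
    def test_converged_with_rhat_near_one(self, small_fit):
        _, fit = small_fit
        assert fit.converged
        assert np.all(fit.rhats < 1.1)
        assert np.all(np.round(fit.rhats, 2) <= 1.01)

    def test_quantiles_monotone(self, small_fit):
        _, fit = small_fit
        s = fit.summary
        assert np.all(s["q2.5"] <= s["q25"])
        assert np.all(s["q25"] <= s["q50"])
        assert np.all(s["q50"] <= s["q75"])
        assert np.all(s["q75"] <= s["q97.5"])

    def test_recovers_generating_values(self, small_fit, reference_params):
        _, fit = small_fit
        truth = reference_params.as_array()
        lo = fit.summary["q2.5"].to_numpy()
        hi = fit.summary["q97.5"].to_numpy()
        inside = (truth >= lo) & (truth <= hi)
        assert inside.sum() >= 5  # allow one marginal miss at this n
        assert np.all((truth >= lo - 0.25 * (hi - lo)) & (truth <= hi + 0.25 * (hi - lo)))

    def test_medians_near_factorized_mle(self, small_fit):
        # at this landscape size the occupied stratum is small, so the
        # posterior is visibly skewed and its median sits a fraction of a
        # posterior SD from the mode (the MLE); the tight Monte-Carlo-error
        # comparison is done at survey scale in the acceptance suite
        data, fit = small_fit
        mle = factorized_mle(data).as_array()
        med = fit.medians.as_array()
        sd = fit.summary["sd"].to_numpy()
        assert np.all(np.abs(med - mle) < 0.25 * sd)

    def test_draw_shape_matches_settings(self, small_fit):
        _, fit = small_fit
        assert fit.draws.shape == (3, 1000, 6)
        frame = fit.posterior_frame()
        assert list(frame.columns) == [
            "chain", "iter", "phi0", "phi_d", "phi_h", "gam0", "gam_d", "gam_h", "loglik",
        ]
        assert len(frame) == 3000

    def test_waic_consistent_with_deviance(self, small_fit):
        _, fit = small_fit
        dev_per_2n = fit.deviance["mean"] / (2 * fit.n_obs)
        assert fit.waic_per_obs == pytest.approx(dev_per_2n, rel=0.2)

    def test_empty_stratum_rejected(self):
        data = TransitionData(
            x1978=np.ones(20, dtype=int),
            x2003=np.random.default_rng(0).integers(0, 2, 20),
            d=np.zeros(20),
            h=np.zeros(20),
        )
        with pytest.raises(ValueError, match="stratum"):
            fit_dynamics_mcmc(data, seed=0)
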