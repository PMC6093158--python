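"""Synthetic landscape generators, occupancy simulators, scenario bundles."""

import numpy as np
import pytest
from scipy.special import expit

from rangedyn.grid import NeighborhoodSpec, build_neighbor_index, neighborhood_occupancy
from rangedyn.habitat import fit_habitat, suitability
from rangedyn.dynamics import TransitionData, fit_dynamics_mcmc, transition_probability
from rangedyn.projection import STEP_YEARS
from rangedyn.synthetic import (
    LandscapeConfig,
    TrendConfig,
    generate_bundle,
    generate_landscape,
    generate_scenarios,
    make_fixture,
    simulate_initial_occupancy,
    simulate_transition,
)


def _morans_i(grid, values):
    """Rook-adjacency Moran's I (direct double-sum formula)."""
    idx = build_neighbor_index(grid, 5.1)
    z = values - values.mean()
    num = s0 = 0.0
    for i in range(grid.n):
        nb, _ = idx.neighbors(i)
        num += (z[i] * z[nb]).sum()
        s0 += nb.size
    return grid.n / s0 * num / (z**2).sum()


@pytest.fixture(scope="module")
def landscape():
    return generate_landscape(LandscapeConfig(n_rows=40, n_cols=40, seed=2))


class TestGenerateLandscape:
    def test_tables_satisfy_invariants(self, landscape):
        grid, env78, env03 = landscape
        for env in (env78, env03):
            assert env.n == grid.n
            closure = env.fr + env.ws + env.ag + env.bt
            assert np.all(closure <= 1 + 1e-9)
            assert np.all((env.scp >= 0) & (env.scp <= 366))
            assert np.all(env.msd >= 0)

    def test_two_regions_present(self, landscape):
        grid, _, _ = landscape
        assert set(grid.region) == {"hokkaido", "other"}
        # Hokkaido occupies the northern rows
        north = grid.y_km[grid.region == "hokkaido"].min()
        assert north > grid.y_km[grid.region == "other"].max() - 1e-9

    def test_snow_field_spatially_autocorrelated(self, landscape):
        grid, env78, _ = landscape
        assert _morans_i(grid, env78.scp) > 0.3

    def test_snow_declines_between_epochs(self, landscape):
        _, env78, env03 = landscape
        assert env03.scp.mean() < env78.scp.mean()

    def test_determinism_and_seed_sensitivity(self):
        cfg = LandscapeConfig(n_rows=12, n_cols=12, seed=5)
        _, a78, _ = generate_landscape(cfg)
        _, b78, _ = generate_landscape(cfg)
        np.testing.assert_array_equal(a78.scp, b78.scp)
        _, c78, _ = generate_landscape(LandscapeConfig(n_rows=12, n_cols=12, seed=6))
        assert not np.array_equal(a78.scp, c78.scp)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_rows=1, n_cols=12)


class TestSimulateOccupancy:
    def test_hopeless_habitat_stays_empty(self, reference_model):
        grid, env78, _ = generate_landscape(LandscapeConfig(n_rows=10, n_cols=10, seed=7))
        bad = reference_model.coefficients.copy()
        bad["intercept"] = -50.0
        from rangedyn.habitat import HabitatModel

        model = HabitatModel(
            formula=reference_model.formula,
            coefficients=bad,
            stderr=reference_model.stderr,
            loglik=0.0,
            n=0,
        )
        # land-use/slope terms cannot overcome a -50 intercept here
        occ = simulate_initial_occupancy(model, env78, grid, seed=8)
        assert occ.x.sum() == 0

    def test_prevalence_concentrates_on_mean_probability(self, reference_model):
        grid, env78, _ = generate_landscape(
            LandscapeConfig(n_rows=124, n_cols=124, seed=9)
        )
        occ = simulate_initial_occupancy(reference_model, env78, grid, seed=10)
        p = expit(suitability(reference_model, env78, grid).h)
        sd = np.sqrt(np.sum(p * (1 - p))) / grid.n
        assert abs(occ.prevalence - p.mean()) < 3 * sd

    def test_fixture_prevalence_plausible(self, fixture_bundle):
        assert 0.05 < fixture_bundle.occ1978.prevalence < 0.95

    def test_persistence_fraction_concentrates(
        self, reference_model, reference_params
    ):
        grid, env78, env03 = generate_landscape(
            LandscapeConfig(n_rows=90, n_cols=90, seed=11)
        )
        occ78 = simulate_initial_occupancy(reference_model, env78, grid, seed=12)
        d = neighborhood_occupancy(occ78, grid, NeighborhoodSpec(25, 2))
        h = suitability(reference_model, env03, grid).h
        occ03 = simulate_transition(reference_params, occ78, d, h, seed=13)
        pres = occ78.x == 1
        assert pres.sum() > 500
        phi = transition_probability(reference_params, 1, d[pres], h[pres])
        expected = phi.mean()
        sd = np.sqrt(np.sum(phi * (1 - phi))) / pres.sum()
        observed = occ03.x[pres].mean()
        assert abs(observed - expected) < 3 * sd

    def test_all_occupied_start_is_well_defined(self, reference_params, rng):
        from rangedyn.grid import OccupancyField

        n = 30
        occ = OccupancyField(year="1978", x=np.ones(n, dtype=int))
        out = simulate_transition(
            reference_params, occ, rng.random(n), rng.normal(size=n), seed=1
        )
        assert out.n == n
        assert set(np.unique(out.x)) <= {0, 1}


@pytest.fixture(scope="module")
def scenarios():
    _, _, env03 = generate_landscape(LandscapeConfig(n_rows=15, n_cols=15, seed=14))
    return env03, generate_scenarios(env03, TrendConfig())


class TestGenerateScenarios:
    def test_group_member_counts_match_design(self, scenarios):
        _, scen = scenarios
        assert scen["baseline"].n_members == 1
        assert scen["lu_only"].n_members == 9
        assert scen["cl_only"].n_members == 4
        assert scen["lucl"].n_members == 36

    def test_baseline_tables_equal_2003(self, scenarios):
        env03, scen = scenarios
        for steps in scen["baseline"].members.values():
            for y in STEP_YEARS:
                np.testing.assert_array_equal(steps[y].scp, env03.scp)
                np.testing.assert_array_equal(steps[y].fr, env03.fr)

    def test_lu_only_leaves_snow_untouched(self, scenarios):
        env03, scen = scenarios
        for steps in scen["lu_only"].members.values():
            for y in STEP_YEARS:
                np.testing.assert_array_equal(steps[y].scp, env03.scp)
                np.testing.assert_array_equal(steps[y].msd, env03.msd)

    def test_cl_only_leaves_landuse_untouched(self, scenarios):
        env03, scen = scenarios
        for steps in scen["cl_only"].members.values():
            for y in STEP_YEARS:
                np.testing.assert_array_equal(steps[y].ws, env03.ws)

    def test_abandonment_transfer_conserves_landuse_total(self, scenarios):
        env03, scen = scenarios
        total0 = env03.fr + env03.ws + env03.ag + env03.bt
        for steps in scen["lucl"].members.values():
            env = steps[2103]
            total = env.fr + env.ws + env.ag + env.bt
            np.testing.assert_allclose(total, total0, atol=1e-12)


class TestFixture:
    def test_fixture_loads_and_satisfies_invariants(self, fixture_bundle):
        b = fixture_bundle
        assert b.grid.n <= 100
        assert b.env1978.n == b.grid.n == b.occ1978.n == b.occ2003.n

    def test_fixture_is_deterministic(self, fixture_bundle):
        again = make_fixture()
        np.testing.assert_array_equal(again.occ1978.x, fixture_bundle.occ1978.x)
        np.testing.assert_array_equal(again.env2003.scp, fixture_bundle.env2003.scp)

    @pytest.mark.parametrize("p,expected", [(0, 0.5), (1, 2 / 3), (2, 0.8)])
    def test_fixture_focal_cell_dispersal_values(self, fixture_bundle, p, expected):
        d = neighborhood_occupancy(
            fixture_bundle.occ1978, fixture_bundle.grid, NeighborhoodSpec(10, p)
        )
        assert d[fixture_bundle.grid.n - 3] == pytest.approx(expected, abs=1e-12)
        assert d[fixture_bundle.grid.n - 1] == 0.0  # isolated cell

    def test_fixture_pipeline_smoke(self, fixture_bundle, reference_model):
        """The whole chain runs on the 68-cell fixture in a few seconds."""
        b = fixture_bundle
        refit = fit_habitat(
            b.occ1978, b.env1978, b.grid,
            type(reference_model.formula)(include_lu=False, climate="scp", include_topo=True),
        )
        h = suitability(refit, b.env2003, b.grid).h
        d = neighborhood_occupancy(b.occ1978, b.grid, NeighborhoodSpec(10, 2))
        data = TransitionData(b.occ1978.x, b.occ2003.x, d, h)
        fit = fit_dynamics_mcmc(data, chains=2, iterations=150, burnin=50, seed=3)
        assert np.isfinite(fit.waic_per_obs)


class TestEndToEndRecovery:
    def test_known_parameters_recovered_across_replicates(
        self, reference_model, reference_params
    ):
        """Generate -> fit habitat -> fit dynamics, 10 seeded replicates:
        aggregate coverage of the generating values by the 95% intervals
        is at least 90%."""
        hits = trials = 0
        spec = NeighborhoodSpec(25, 2)
        for rep in range(10):
            bundle = generate_bundle(
                LandscapeConfig(n_rows=64, n_cols=64, seed=100 + rep),
                reference_model,
                reference_params,
                spec,
                seed=100 + rep,
            )
            refit = fit_habitat(
                bundle.occ1978, bundle.env1978, bundle.grid, reference_model.formula
            )
            for term, truth in reference_model.coefficients.items():
                est, se = refit.coefficients[term], refit.stderr[term]
                hits += abs(est - truth) <= 1.96 * se
                trials += 1
            d = neighborhood_occupancy(bundle.occ1978, bundle.grid, spec)
            h = suitability(refit, bundle.env2003, bundle.grid).h
            data = TransitionData(bundle.occ1978.x, bundle.occ2003.x, d, h)
            fit = fit_dynamics_mcmc(
                data, chains=3, iterations=500, burnin=100, seed=200 + rep,
                compute_waic=False,
            )
            truth6 = reference_params.as_array()
            lo = fit.summary["q2.5"].to_numpy()
            hi = fit.summary["q97.5"].to_numpy()
            hits += int(((truth6 >= lo) & (truth6 <= hi)).sum())
            trials += 6
        assert hits / trials >= 0.9, (hits, trials)
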