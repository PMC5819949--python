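"""Global fitting, chi-square surfaces and bootstrap uncertainty."""

import numpy as np
import pytest

from chexflux.bloch_mcconnell import ZzDataset
from chexflux.exchange_model import ValidationError
from chexflux.fitting import (
    NetworkSpec,
    ParameterSpec,
    bootstrap,
    build_network_from_params,
    chi2_surface_1d,
    fit_model,
    population_distributions,
)
from chexflux.synthetic_data import (
    generate_cest_dataset,
    generate_zz_dataset,
    r17_zz_scenario,
    sh3_cest4_scenario,
)

TWO_STATE = NetworkSpec(("U", "B"), (("U", "B"),), "rates", ligand_conc=500e-6)
TWO_STATE_PARAMS = (
    ParameterSpec("k_U_B", 0.3, 0.01, 50.0),
    ParameterSpec("k_B_U", 1.0, 0.01, 50.0),
    ParameterSpec("r1_Met26", 2.0, vary=False),
)

FOUR_STATE = NetworkSpec(
    ("N", "U", "B1", "B2"),
    (("N", "U"), ("U", "B1"), ("N", "B1"), ("U", "B2"), ("N", "B2")),
    "kex_pop",
    ligand_conc=500e-6,
)


def four_state_params():
    fixed_shifts = [
        ParameterSpec(f"shift_Ile27_{s}", v, vary=False)
        for s, v in (("N", 0.55), ("U", 0.70), ("B1", 0.20), ("B2", 0.35))
    ]
    return (
        ParameterSpec("kex_N_U", 2.0, 0.05, 50.0),
        ParameterSpec("kex_U_B1", 2.0, 0.05, 50.0),
        ParameterSpec("kex_N_B1", 2.0, 0.05, 50.0),
        ParameterSpec("kex_U_B2", 2.0, 0.05, 50.0),
        ParameterSpec("kex_N_B2", 2.0, 0.05, 50.0),
        ParameterSpec("logp_N", 0.0, vary=False),
        ParameterSpec("logp_U", 0.3, -6.0, 6.0),
        ParameterSpec("logp_B1", -1.0, -6.0, 6.0),
        ParameterSpec("logp_B2", -1.5, -6.0, 6.0),
        *fixed_shifts,
        ParameterSpec("r1_Ile27", 1.5, vary=False),
        ParameterSpec("r2_Ile27", 25.0, vary=False),
    )


class TestFitModel:
    def test_noiseless_zz_exact_recovery(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.0))
        fit = fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=3, seed=0)
        assert fit.success
        assert fit.params["k_U_B"] == pytest.approx(0.8, abs=1e-6)
        assert fit.params["k_B_U"] == pytest.approx(2.7, abs=1e-6)

    def test_noisy_zz_recovery_over_seeds(self):
        """Mean recovered rates over noisy realizations stay within the
        one-sigma envelope 0.8 +/- 0.1 and 2.7 +/- 0.2 (study schedule:
        13 mixing times 25-800 ms, 2% noise).  A 25-seed version of the
        full 100-seed check."""
        k_ub, k_bu = [], []
        for seed in range(25):
            ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=seed))
            fit = fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=1, seed=0)
            k_ub.append(fit.params["k_U_B"])
            k_bu.append(fit.params["k_B_U"])
        assert abs(np.mean(k_ub) - 0.8) < 0.1
        assert abs(np.mean(k_bu) - 2.7) < 0.2

    def test_noiseless_four_state_cest_recovery(self):
        """Global CEST fit on noiseless four-state data recovers every
        exchange rate to better than 0.1% relative error."""
        scen = sh3_cest4_scenario(noise_sd=0.0)
        datasets = list(generate_cest_dataset(scen).values())
        fit = fit_model(datasets, FOUR_STATE, four_state_params(), n_starts=1, seed=0)
        truth = {
            "kex_N_U": 1.0,
            "kex_U_B1": 3.0,
            "kex_N_B1": 0.75,
            "kex_U_B2": 4.2,
            "kex_N_B2": 0.2,
        }
        for name, v in truth.items():
            assert fit.params[name] == pytest.approx(v, rel=1e-3)
        net = fit.network()
        assert net.population("N") == pytest.approx(0.44, abs=2e-3)

    def test_determinism(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=3))
        f1 = fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=5, seed=11)
        f2 = fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=5, seed=11)
        assert f1.params == f2.params
        assert f1.chisqr == f2.chisqr

    def test_underdetermined_warning(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.0))
        idx = np.arange(4)  # 4 points for 2 free parameters
        fit = fit_model([ds.subset(idx)], TWO_STATE, TWO_STATE_PARAMS, n_starts=1)
        assert any("underdetermined" in w for w in fit.warnings)

    def test_no_datasets_rejected(self):
        with pytest.raises(ValidationError):
            fit_model([], TWO_STATE, TWO_STATE_PARAMS)


@pytest.fixture(scope="module")
def zz_fit():
    ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.01, seed=8))
    return fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=1, seed=0)


class TestChi2Surface:
    def test_minimum_coincides_with_fit(self, zz_fit):
        grid = np.linspace(0.4, 1.2, 17)
        surf = chi2_surface_1d(zz_fit, "k_U_B", grid)
        v_min, chi_min = surf.minimum()
        step = grid[1] - grid[0]
        assert abs(v_min - zz_fit.params["k_U_B"]) <= step
        assert chi_min <= zz_fit.redchi + 1e-6

    def test_well_determined_rate_rises_steeply(self, zz_fit):
        """chi2_red increases by >= 1 within +/-50% of the minimum for a
        well-determined zz rate constant."""
        best = zz_fit.params["k_U_B"]
        grid = [0.5 * best, best, 1.5 * best]
        surf = chi2_surface_1d(zz_fit, "k_U_B", grid)
        assert not surf.shallow
        assert surf.redchi[0] >= surf.redchi[1] + 1.0
        assert surf.redchi[2] >= surf.redchi[1] + 1.0

    def test_noiseless_surface_is_locally_parabolic(self):
        """Around a noiseless minimum the chi2 profile is a parabola with
        its vertex at the truth."""
        t = np.linspace(0.05, 1.0, 12)
        rate = 2.5
        ds = ZzDataset(
            probe="p",
            origin_state=np.array(["A"] * 12, dtype=object),
            destination_state=np.array(["A"] * 12, dtype=object),
            t_mix_s=t,
            intensity=0.5 * np.exp(-rate * t),
            sigma=np.full(12, 0.01),
        )
        spec = NetworkSpec(("A", "B"), (("A", "B"),), "rates")
        params = (
            ParameterSpec("k_A_B", 1e-9, vary=False),
            ParameterSpec("k_B_A", 10.0, vary=False),
            ParameterSpec("r1_p", 2.0, 0.1, 10.0),
            ParameterSpec("scale_zz_p", 0.5, 0.01, 10.0, vary=False),
        )
        fit = fit_model([ds], spec, params, n_starts=1)
        assert fit.params["r1_p"] == pytest.approx(rate, rel=1e-6)
        grid = rate + np.linspace(-0.02, 0.02, 9)
        surf = chi2_surface_1d(fit, "r1_p", grid)
        c2, c1, _ = np.polyfit(surf.grid, surf.redchi, 2)
        assert c2 > 0
        assert -c1 / (2 * c2) == pytest.approx(rate, abs=1e-3)

    def test_empty_grid_rejected(self, zz_fit):
        with pytest.raises(ValidationError):
            chi2_surface_1d(zz_fit, "k_U_B", [])

    def test_fixed_parameter_rejected(self, zz_fit):
        with pytest.raises(ValidationError):
            chi2_surface_1d(zz_fit, "r1_Met26", [1.0, 2.0])


class TestShallowSurface:
    def test_population_surface_flat_in_cest_only_fit(self):
        """Populations are weakly determined by CEST data when the
        rates carry the information; the surface is flagged shallow."""
        scen = sh3_cest4_scenario(noise_sd=0.01, seed=2)
        datasets = [generate_cest_dataset(scen)["U"]]
        # single profile: population log-weights are barely constrained
        fit = fit_model(datasets, FOUR_STATE, four_state_params(), n_starts=1, seed=0)
        grid = np.linspace(-0.3, 0.3, 5) + fit.params["logp_B2"]
        surf = chi2_surface_1d(fit, "logp_B2", grid)
        assert surf.shallow


class TestBootstrap:
    def test_determinism(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=4))
        b1 = bootstrap([ds], TWO_STATE, TWO_STATE_PARAMS, n_replicates=10, seed=5)
        b2 = bootstrap([ds], TWO_STATE, TWO_STATE_PARAMS, n_replicates=10, seed=5)
        assert np.array_equal(b1.distributions["k_U_B"], b2.distributions["k_U_B"])

    def test_decay_rate_sd_matches_fisher_information(self):
        """Bootstrap SD of a single-exponential decay rate agrees with the
        closed-form (Fisher-information) standard error within 20%."""
        rng = np.random.default_rng(12)
        n = 40
        t = np.linspace(0.02, 1.0, n)
        sigma = 0.01
        amp, rate = 0.9, 2.0
        clean = amp * np.exp(-rate * t)
        y = clean + rng.normal(0, sigma, n)
        ds = ZzDataset(
            probe="p",
            origin_state=np.array(["A"] * n, dtype=object),
            destination_state=np.array(["A"] * n, dtype=object),
            t_mix_s=t,
            intensity=y,
            sigma=np.full(n, sigma),
        )
        spec = NetworkSpec(("A", "B"), (("A", "B"),), "rates")
        params = (
            ParameterSpec("k_A_B", 1e-9, vary=False),
            ParameterSpec("k_B_A", 10.0, vary=False),
            ParameterSpec("r1_p", 1.0, 0.1, 10.0),
            ParameterSpec("scale_zz_p", 1.0, 0.01, 10.0),
        )
        fit = fit_model([ds], spec, params, n_starts=1)
        assert fit.params["r1_p"] == pytest.approx(rate, rel=0.05)
        boot = bootstrap(
            [ds], spec, params, n_replicates=200, seed=99, start_from=fit.params
        )
        # Fisher SE for (amp, rate) in I = a*exp(-r*t) with known sigma
        J = np.column_stack([np.exp(-rate * t), -amp * t * np.exp(-rate * t)])
        cov = sigma**2 * np.linalg.inv(J.T @ J)
        se_rate = np.sqrt(cov[1, 1])
        assert boot.sd["r1_p"] == pytest.approx(se_rate, rel=0.2)

    def test_zz_bootstrap_sd_matches_across_seed_scatter(self):
        """Bootstrap SDs are consistent with the across-realization SD of
        the estimator within a factor of 1.5."""
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=21))
        fit = fit_model([ds], TWO_STATE, TWO_STATE_PARAMS, n_starts=1)
        boot = bootstrap(
            [ds],
            TWO_STATE,
            TWO_STATE_PARAMS,
            n_replicates=60,
            seed=1,
            start_from=fit.params,
        )
        across = []
        for seed in range(30):
            d = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=100 + seed))
            f = fit_model([d], TWO_STATE, TWO_STATE_PARAMS, n_starts=1)
            across.append(f.params["k_U_B"])
        sd_across = np.std(across, ddof=1)
        assert boot.sd["k_U_B"] / sd_across < 1.5
        assert sd_across / boot.sd["k_U_B"] < 1.5

    def test_point_counts_preserved(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=6))
        sub = ds.subset(np.random.default_rng(0).integers(0, ds.n_points, ds.n_points))
        assert sub.n_points == ds.n_points

    def test_too_few_replicates_rejected(self):
        ds = generate_zz_dataset(r17_zz_scenario(noise_sd=0.02, seed=6))
        with pytest.raises(ValidationError):
            bootstrap([ds], TWO_STATE, TWO_STATE_PARAMS, n_replicates=1)


class TestPopulationDistributions:
    def test_softmax_draws_sum_to_one(self):
        scen = sh3_cest4_scenario(noise_sd=0.01, seed=1)
        datasets = list(generate_cest_dataset(scen).values())
        fit = fit_model(datasets, FOUR_STATE, four_state_params(), n_starts=1)
        boot = bootstrap(
            datasets,
            FOUR_STATE,
            four_state_params(),
            n_replicates=5,
            seed=2,
            start_from=fit.params,
        )
        pops = population_distributions(FOUR_STATE, boot, fit.params)
        total = sum(pops[s] for s in FOUR_STATE.states)
        assert np.allclose(total, 1.0)


class TestBuildNetwork:
    def test_kex_pop_network_satisfies_detailed_balance(self):
        params = {
            "kex_N_U": 1.0,
            "kex_U_B1": 3.0,
            "kex_N_B1": 0.75,
            "kex_U_B2": 4.2,
            "kex_N_B2": 0.2,
            "logp_N": 0.0,
            "logp_U": 0.0,
            "logp_B1": -1.7047,
            "logp_B2": -2.3979,
        }
        net = build_network_from_params(FOUR_STATE, params)
        for (i, j) in FOUR_STATE.edges:
            assert net.kex(i, j) == pytest.approx(params[f"kex_{i}_{j}"])
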