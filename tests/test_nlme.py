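"""Mixed-effects estimation: objective, EBEs, shrinkage, fitting, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from nanotrans.kinetics import InitialCondition, KineticRates, solve
from nanotrans.nlme import (ModelSpec, PopulationParameters,
                            TranslocationDataset, anova_by_time,
                            empirical_bayes, eta_shrinkage, fit,
                            marginal_objective, marginal_objective_quadrature,
                            species_anova)
from nanotrans.synth import AU_STUDY_DESIGN, StudyDesign, generate_translocation


def _params(phi=0.69, omega2=0.0, sigma1=0.1, sigma2=0.01, **rates):
    defaults = {"k12": 0.002, "k21": 0.005, "k23": 0.007, "k32": 0.003}
    defaults.update(rates)
    return PopulationParameters(phi=phi, omega2=omega2,
                                rates=KineticRates(**defaults),
                                sigma1=sigma1, sigma2=sigma2)


class TestMarginalObjective:
    def test_omega_zero_equals_weighted_least_squares(self, small_dataset):
        """With no random effect the objective is the plain fixed-effects
        -2LL under the combined error model, written out independently."""
        params = _params(phi=0.66, omega2=0.0)
        value = marginal_objective(params, small_dataset,
                                   ModelSpec(eta_phi=False))
        expected = 0.0
        for _, row in small_dataset.frame.iterrows():
            traj = solve(params.rates, InitialCondition(params.phi),
                         [0.0, row["time_min"]])
            col = {"apical": 0, "basolateral": 2}[row["compartment"]]
            pred = traj.fractions[1, col]
            var = params.sigma1**2 * pred**2 + params.sigma2**2
            r = row["fraction"] - pred
            expected += math.log(2 * math.pi * var) + r * r / var
        assert value == pytest.approx(expected, rel=1e-10)

    def test_single_species_matches_quadrature(self):
        """Laplace approximation within 0.1 of 41-node adaptive quadrature
        for a one-dimensional species effect."""
        params = _params(phi=0.6, omega2=0.05**2, sigma1=0.1, sigma2=0.01)
        data = generate_translocation(
            params, StudyDesign(applied_conc_per_l={"only": 1e10},
                                times_min=(10.0, 30.0, 60.0, 240.0),
                                replicates=3), seed=3)
        lap = marginal_objective(params, data, ModelSpec(eta_phi=True))
        quad = marginal_objective_quadrature(params, data, n_nodes=41)
        assert abs(lap - quad) <= 0.1

    def test_quadrature_agreement_on_random_draws(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            params = _params(phi=rng.uniform(0.45, 0.8),
                             omega2=rng.uniform(0.02, 0.1) ** 2,
                             sigma1=rng.uniform(0.05, 0.2),
                             sigma2=rng.uniform(0.005, 0.02),
                             k12=rng.uniform(0.001, 0.01),
                             k21=rng.uniform(0.001, 0.01),
                             k23=rng.uniform(0.001, 0.01),
                             k32=rng.uniform(0.001, 0.01))
            data = generate_translocation(params, seed=50 + i)
            lap = marginal_objective(params, data, ModelSpec(eta_phi=True))
            quad = marginal_objective_quadrature(params, data)
            assert abs(lap - quad) <= 0.1

    def test_sigma_doubling_identity(self, small_dataset):
        """Doubling both residual SDs at fixed predictions adds 2*N*ln(2)
        and rescales the quadratic form by 1/4 (Gaussian -2LL algebra)."""
        p1 = _params(phi=0.66, sigma1=0.08, sigma2=0.008)
        p2 = _params(phi=0.66, sigma1=0.16, sigma2=0.016)
        v1 = marginal_objective(p1, small_dataset, ModelSpec(eta_phi=False))
        v2 = marginal_objective(p2, small_dataset, ModelSpec(eta_phi=False))
        # quadratic part from the closed-form residual sum
        quad = 0.0
        for _, row in small_dataset.frame.iterrows():
            traj = solve(p1.rates, InitialCondition(p1.phi),
                         [0.0, row["time_min"]])
            col = {"apical": 0, "basolateral": 2}[row["compartment"]]
            pred = traj.fractions[1, col]
            var = p1.sigma1**2 * pred**2 + p1.sigma2**2
            quad += (row["fraction"] - pred) ** 2 / var
        n = len(small_dataset)
        assert v2 - v1 == pytest.approx(2 * n * math.log(2) - 0.75 * quad,
                                        rel=1e-10)

    def test_duplicated_dataset_doubles_fixed_effects_objective(
            self, small_dataset):
        params = _params(phi=0.66)
        doubled = TranslocationDataset(
            pd.concat([small_dataset.frame, small_dataset.frame],
                      ignore_index=True))
        v1 = marginal_objective(params, small_dataset, ModelSpec(eta_phi=False))
        v2 = marginal_objective(params, doubled, ModelSpec(eta_phi=False))
        assert v2 == pytest.approx(2 * v1, rel=1e-12)


class TestRateRandomEffects:
    def test_lognormal_rate_effect_path(self):
        """The optional log-normal between-species effect on a transfer
        constant produces a finite objective that beats a mis-specified
        fixed-rates model on data generated with rate heterogeneity."""
        base = _params(phi=0.69, omega2=0.0, sigma1=0.05, sigma2=0.005)
        gen = PopulationParameters(phi=0.69, omega2=0.0, rates=base.rates,
                                   sigma1=0.05, sigma2=0.005,
                                   rate_omega2={"k12": 0.3**2})
        data = generate_translocation(gen, seed=21)
        with_re = marginal_objective(gen, data,
                                     ModelSpec(eta_phi=False,
                                               eta_rates=("k12",)))
        without = marginal_objective(base, data, ModelSpec(eta_phi=False))
        assert np.isfinite(with_re)
        assert with_re < without

    def test_rate_effect_ebes_have_matching_dimension(self):
        params = PopulationParameters(
            phi=0.69, omega2=0.05**2,
            rates=KineticRates(0.002, 0.005, 0.007, 0.003),
            sigma1=0.1, sigma2=0.01, rate_omega2={"k23": 0.2**2})
        data = generate_translocation(params, seed=22)
        eta = empirical_bayes(params, data, data.species[0])
        assert eta.shape == (2,)  # phi effect + k23 effect
        assert np.all(np.isfinite(eta))


class TestEmpiricalBayes:
    def test_species_without_data_gets_prior_mode(self, small_dataset):
        params = _params(omega2=0.05**2)
        eta = empirical_bayes(params, small_dataset, "absent-species")
        assert eta == pytest.approx(np.zeros(1))

    def test_undefined_without_random_effect(self, small_dataset):
        with pytest.raises(ValueError):
            empirical_bayes(_params(omega2=0.0), small_dataset, "A")

    def test_symmetric_species_get_opposite_ebes(self):
        """Two species mirrored about the population mean have equal and
        opposite conditional modes."""
        params = _params(phi=0.6, omega2=0.1**2, sigma1=0.0, sigma2=0.02)
        base = solve(params.rates, InitialCondition(1.0),
                     [0.0, 30.0, 240.0]).fractions
        rows = []
        for species, f in (("lo", 0.55), ("hi", 0.65)):
            for j, t in enumerate((30.0, 240.0)):
                for comp, col in (("apical", 0), ("basolateral", 2)):
                    rows.append({"species": species, "replicate": 1,
                                 "time_min": t, "compartment": comp,
                                 "fraction": f * base[j + 1, col]})
        data = TranslocationDataset(pd.DataFrame(rows))
        lo = empirical_bayes(params, data, "lo")[0]
        hi = empirical_bayes(params, data, "hi")[0]
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_large_omega_limit_is_least_squares_offset(self):
        """As the prior flattens, the EBE approaches the per-species
        maximum-likelihood offset (computed by an independent profile fit)."""
        from scipy.optimize import minimize_scalar

        params = _params(phi=0.6, omega2=10.0**2, sigma1=0.0, sigma2=0.02)
        data = generate_translocation(
            _params(phi=0.72, sigma1=0.0, sigma2=0.02),
            StudyDesign(applied_conc_per_l={"s": 1e10},
                        times_min=(30.0, 240.0), replicates=3), seed=5)
        eta = empirical_bayes(params, data, "s")[0]
        base = solve(params.rates, InitialCondition(1.0),
                     [0.0, 30.0, 240.0]).fractions
        col = {"apical": 0, "basolateral": 2}
        preds = {(t, c): base[j + 1, col[c]]
                 for j, t in enumerate((30.0, 240.0)) for c in col}

        def sse(f):
            return sum((row["fraction"]
                        - f * preds[(row["time_min"], row["compartment"])]) ** 2
                       for _, row in data.frame.iterrows())

        ls = minimize_scalar(sse, bounds=(0.01, 1.0), method="bounded").x
        assert params.phi + eta == pytest.approx(ls, abs=1e-3)


class TestEtaShrinkage:
    def test_all_zero_ebes_full_shrinkage(self):
        assert eta_shrinkage([0.0, 0.0, 0.0], omega=0.1) == 1.0

    def test_sd_equal_to_omega_no_shrinkage(self):
        ebes = [-0.1, 0.1]
        sd = np.std(ebes, ddof=1)
        assert eta_shrinkage(ebes, omega=sd) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        # SD({-0.1, 0.1}, n-1) = 0.141421; 1 - 0.141421/0.2 = 0.292893
        assert eta_shrinkage([-0.1, 0.1], omega=0.2) == pytest.approx(
            0.2928932, abs=1e-6)

    def test_requires_two_ebes_and_positive_omega(self):
        with pytest.raises(ValueError):
            eta_shrinkage([0.1], omega=0.2)
        with pytest.raises(ValueError):
            eta_shrinkage([0.1, -0.1], omega=0.0)


class TestFit:
    def test_noise_free_recovery(self):
        """Near-noiseless data returns the generating parameters."""
        true = _params(phi=0.69, sigma1=0.0, sigma2=1e-4)
        data = generate_translocation(true, AU_STUDY_DESIGN, seed=7)
        res = fit(data, spec=ModelSpec(eta_phi=False), seed=0, n_starts=2)
        assert res.converged
        assert res.params.phi == pytest.approx(0.69, abs=0.005)
        for name in ("k12", "k21", "k23", "k32"):
            assert getattr(res.params.rates, name) == pytest.approx(
                getattr(true.rates, name), rel=0.05)

    def test_sigma2_only_noise_phi_within_mc_error(self):
        """omega = 0, additive-only noise, large n: phi lands within 3
        Monte-Carlo standard errors of the generating value."""
        true = _params(phi=0.69, sigma1=0.0, sigma2=0.01)
        design = StudyDesign(applied_conc_per_l={f"s{i}": 1e10 for i in range(4)},
                             times_min=(10.0, 30.0, 60.0, 240.0), replicates=20)
        data = generate_translocation(true, design, seed=11)
        res = fit(data, spec=ModelSpec(eta_phi=False), seed=0, n_starts=1)
        # 320 apical observations with additive SD 0.01 pin phi to roughly
        # 0.01/sqrt(320) ~ 6e-4 up to the design factor; 3 MC SEs << 0.01
        assert abs(res.params.phi - 0.69) <= 0.01

    def test_duplicated_dataset_same_estimates(self, small_dataset):
        doubled = TranslocationDataset(
            pd.concat([small_dataset.frame, small_dataset.frame],
                      ignore_index=True))
        r1 = fit(small_dataset, spec=ModelSpec(eta_phi=False), seed=0,
                 n_starts=1)
        r2 = fit(doubled, spec=ModelSpec(eta_phi=False), seed=0, n_starts=1)
        assert r2.params.phi == pytest.approx(r1.params.phi, abs=1e-3)
        assert r2.neg2ll == pytest.approx(2 * r1.neg2ll, rel=1e-3)

    def test_random_effect_collapses_on_null_data(self):
        """Fitting the species effect to data generated without one reports
        collapse (threshold or failed likelihood-ratio test) in >= 90%."""
        true = _params(phi=0.69, omega2=0.0, sigma1=0.15, sigma2=0.01)
        collapsed = 0
        n = 20
        for seed in range(n):
            data = generate_translocation(true, AU_STUDY_DESIGN, seed=seed)
            res = fit(data, seed=0, n_starts=1, maxiter=1000)
            collapsed += res.collapsed
        assert collapsed >= 0.9 * n

    def test_fit_requires_two_times(self):
        frame = pd.DataFrame([
            {"species": "a", "replicate": r, "time_min": 60.0,
             "compartment": "apical", "fraction": 0.6} for r in range(3)])
        with pytest.raises(ValueError):
            fit(TranslocationDataset(frame))

    def test_yaml_serialisation(self, small_dataset, tmp_path):
        res = fit(small_dataset, spec=ModelSpec(eta_phi=False), seed=0,
                  n_starts=1)
        path = tmp_path / "fit.yaml"
        res.to_yaml(path)
        import yaml

        doc = yaml.safe_load(path.read_text())
        assert doc["estimates"]["phi"] == pytest.approx(res.params.phi)
        assert doc["n_obs"] == len(small_dataset)


class TestSpeciesAnova:
    def test_zero_within_group_variance_degenerate(self):
        rows = []
        for species, val in (("a", 1.0), ("b", 2.0)):
            for rep in range(3):
                rows.append({"species": species, "replicate": rep,
                             "time_min": 60.0, "compartment": "apical",
                             "fraction": val})
        data = TranslocationDataset(pd.DataFrame(rows))
        assert species_anova(data, 60.0, "apical") == 0.0

    def test_identical_constant_groups(self):
        rows = [{"species": s, "replicate": r, "time_min": 60.0,
                 "compartment": "apical", "fraction": 1.0}
                for s in "ab" for r in range(3)]
        data = TranslocationDataset(pd.DataFrame(rows))
        assert species_anova(data, 60.0, "apical") == 1.0

    def test_insufficient_replication_rejected(self):
        rows = [{"species": "a", "replicate": 1, "time_min": 60.0,
                 "compartment": "apical", "fraction": 1.0},
                {"species": "b", "replicate": 1, "time_min": 60.0,
                 "compartment": "apical", "fraction": 2.0}]
        data = TranslocationDataset(pd.DataFrame(rows))
        with pytest.raises(ValueError):
            species_anova(data, 60.0, "apical")

    def test_null_rejection_rate(self):
        """Same-distribution groups reject at ~5%."""
        rng = np.random.default_rng(3)
        rej = 0
        n = 400
        for _ in range(n):
            rows = [{"species": f"s{s}", "replicate": r, "time_min": 60.0,
                     "compartment": "apical",
                     "fraction": rng.normal(0.5, 0.1)}
                    for s in range(3) for r in range(3)]
            data = TranslocationDataset(pd.DataFrame(rows))
            rej += species_anova(data, 60.0, "apical") < 0.05
        assert rej / n == pytest.approx(0.05, abs=0.03)

    def test_holm_adjustment_monotone(self):
        data = generate_translocation(seed=2)
        table = anova_by_time(data, "basolateral")
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()
        assert set(table["time_min"]) == {10.0, 30.0, 60.0, 240.0}
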