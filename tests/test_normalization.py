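import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.sparse as sp

from fleecerot.mme import RandomTerm, SingularSystemError, solve_mme
from fleecerot.normalization import (FitOptions, ModelSpec, VarianceComponents,
                                     fit_mixed_model, reml_loglik)
from fleecerot.simulate import ArraySimConfig, simulate_intensities

from oracles import dense_designs, dense_reml_loglik, gls_solutions

COMPS = VarianceComponents(0.4, 0.1, 0.2, 0.15, 0.3, 0.25)


class TestVarianceComponents:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-0.1, 1, 1, 1, 1, 1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(np.nan, 1, 1, 1, 1, 1)

    def test_array_round_trip(self):
        assert VarianceComponents.from_array(COMPS.as_array()) == COMPS


class TestAgainstDenseOracle:
    def test_restricted_loglik_matches_dense(self, tiny_array_obs):
        obs, _ = tiny_array_obs
        y, W, Zs, _ = dense_designs(obs)
        expect = dense_reml_loglik(y, W, Zs, COMPS.random_array(), COMPS.sigma2_e)
        got = reml_loglik(obs, COMPS)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_blups_match_gls(self, tiny_array_obs):
        """BLUPs from the blocked MME equal sigma2_k Z_k' P y on dense V."""
        from fleecerot.normalization import _GeneBlocked

        obs, _ = tiny_array_obs
        y, W, Zs, _ = dense_designs(obs)
        _, us = gls_solutions(y, W, Zs, COMPS.random_array(), COMPS.sigma2_e)
        gb = _GeneBlocked(obs)
        ev = gb.evaluate(COMPS)
        for k in range(5):
            lo = gb.offsets[k]
            width = gb.sizes[k]
            blocked = ev["u"][:, lo:lo + width].reshape(-1)
            np.testing.assert_allclose(blocked, us[k], atol=1e-6)

    def test_converged_point_matches_nelder_mead_on_dense_criterion(self):
        """On a tiny instance the REML optimum agrees with direct
        maximisation of the dense restricted likelihood."""
        cfg = ArraySimConfig(
            n_genes=2, n_blocks_per_array=1,
            treatments=("RH0", "SH0"), n_replicates=2,
            flocks=("Trangie", "CSIRO"),
            true_components=VarianceComponents(0.5, 0.2, 0.2, 0.2, 0.5, 0.3),
            seed=7)
        obs, _ = simulate_intensities(cfg)
        fit = fit_mixed_model(obs)
        y, W, Zs, _ = dense_designs(obs)

        def neg(logv):
            v = np.exp(logv)
            return -dense_reml_loglik(y, W, Zs, v[:5], v[5])

        res = scipy.optimize.minimize(
            neg, np.log(np.maximum(fit.components.as_array(), 1e-6)),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)


class TestFitBehaviour:
    def test_identical_observations_floor_components(self):
        cfg = ArraySimConfig(n_genes=3, n_blocks_per_array=1,
                             treatments=("RH0", "SH0"), n_replicates=2,
                             flocks=("Trangie", "CSIRO"),
                             true_components=VarianceComponents(0, 0, 0, 0, 0, 0),
                             sigma_C=0.0, mu=5.0, seed=0)
        obs, _ = simulate_intensities(cfg)
        fit = fit_mixed_model(obs)
        assert np.all(fit.components.as_array() <= 1e-8)
        assert np.all(np.abs(fit.normalized.to_numpy()) < 1e-6)

    def test_shrinkage_monotone_in_residual_variance(self, tiny_array_obs):
        """Inflating sigma2_e at fixed components shrinks the TG solution
        vector toward zero (norm-wise; individual entries may redistribute
        between crossed terms)."""
        from fleecerot.normalization import _GeneBlocked

        obs, _ = tiny_array_obs
        gb = _GeneBlocked(obs)
        norms = []
        for factor in (1.0, 10.0, 100.0, 1e4):
            comps = VarianceComponents.from_array(
                np.append(COMPS.random_array(), COMPS.sigma2_e * factor))
            ev = gb.evaluate(comps)
            norms.append(np.linalg.norm(ev["u"][:, gb.offsets[4]:]))
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-2 * norms[0]

    def test_gene_relabelling_permutes_solutions(self, tiny_array_obs):
        obs, _ = tiny_array_obs
        fit1 = fit_mixed_model(obs)
        relabel = {"g00001": "zz1", "g00002": "aa2", "g00003": "mm3",
                   "g00004": "bb4"}
        obs2 = obs.assign(gene_id=obs["gene_id"].map(relabel))
        fit2 = fit_mixed_model(obs2)
        for old, new in relabel.items():
            np.testing.assert_allclose(
                fit1.normalized.loc[old].to_numpy(),
                fit2.normalized.loc[new].to_numpy(), atol=1e-7)

    def test_optimum_beats_generating_components(self):
        """Restricted likelihood at the fit is >= its value at the truth."""
        wins = 0
        for seed in range(6):
            cfg = ArraySimConfig(n_genes=30, true_components=COMPS, seed=seed)
            obs, truth = simulate_intensities(cfg)
            fit = fit_mixed_model(obs)
            at_truth = reml_loglik(obs, truth.components)
            wins += fit.loglik >= at_truth - 1e-6
        assert wins == 6

    def test_single_level_random_factor_rejected(self, tiny_array_obs):
        obs, _ = tiny_array_obs
        obs = obs.assign(flock_id="onlyflock")
        from fleecerot.normalization import DesignError
        with pytest.raises(DesignError, match="flock"):
            fit_mixed_model(obs)

    def test_treatment_coding_validated(self):
        with pytest.raises(ValueError):
            ModelSpec(treatment_coding="bogus")


class TestSolveMme:
    def _small_system(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z1 = np.zeros((n, 5))
        Z1[np.arange(n), rng.integers(0, 5, n)] = 1
        Z2 = np.zeros((n, 8))
        Z2[np.arange(n), rng.integers(0, 8, n)] = 1
        y = rng.normal(size=n)
        return X, Z1, Z2, y

    def test_matches_gls_oracle(self):
        X, Z1, Z2, y = self._small_system()
        sol = solve_mme(X, [RandomTerm("u1", sp.csr_matrix(Z1), 0.7),
                            RandomTerm("u2", sp.csr_matrix(Z2), 0.3)],
                        sigma2_e=0.5, y=y)
        b, us = gls_solutions(y, X, [Z1, Z2], [0.7, 0.3], 0.5)
        np.testing.assert_allclose(sol.fixed, b, atol=1e-8)
        np.testing.assert_allclose(sol.random["u1"], us[0], atol=1e-8)
        np.testing.assert_allclose(sol.random["u2"], us[1], atol=1e-8)

    def test_large_variance_limit_approaches_fixed_effect_fit(self):
        # lambda -> 0: BLUPs approach the free least-squares deviations
        X, Z1, _, y = self._small_system(seed=1)
        sol = solve_mme(X, [RandomTerm("u", sp.csr_matrix(Z1), 1e8)],
                        sigma2_e=1.0, y=y)
        # residuals after fixed + random fit should be orthogonal to Z columns
        resid = y - X @ sol.fixed - Z1 @ sol.random["u"]
        np.testing.assert_allclose(Z1.T @ resid, 0, atol=1e-4)

    def test_tiny_variance_shrinks_blups_to_zero(self):
        X, Z1, _, y = self._small_system(seed=2)
        sol = solve_mme(X, [RandomTerm("u", sp.csr_matrix(Z1), 1e-10)],
                        sigma2_e=1.0, y=y)
        np.testing.assert_allclose(sol.random["u"], 0, atol=1e-7)

    def test_nonpositive_variance_rejected(self):
        X, Z1, _, y = self._small_system()
        with pytest.raises(ValueError, match="strictly positive"):
            solve_mme(X, [RandomTerm("u", sp.csr_matrix(Z1), 0.0)], 1.0, y)

    def test_singular_fixed_block_named(self):
        X, Z1, _, y = self._small_system()
        X2 = np.column_stack([X, X[:, 0]])  # duplicated column
        with pytest.raises(SingularSystemError):
            solve_mme(X2, [RandomTerm("u", sp.csr_matrix(Z1), 1.0)], 1.0, y)


class TestRecovery:
    def test_components_recovered_within_monte_carlo_error(self, request):
        """20-seed recovery of the generating components (strong treatment
        signal, weak everything else) on the eight-array loop."""
        from conftest import eight_array_loop

        loop, trts = eight_array_loop()
        truth = VarianceComponents(0.05, 0.05, 0.05, 0.05, 0.5, 0.05)
        ests = []
        for seed in range(20):
            cfg = ArraySimConfig(n_genes=200, treatments=trts, loop_design=loop,
                                 true_components=truth, seed=seed)
            obs, _ = simulate_intensities(cfg)
            fit = fit_mixed_model(obs)
            assert fit.converged
            ests.append(fit.components.as_array())
        ests = np.array(ests)
        mean = ests.mean(axis=0)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        np.testing.assert_array_less(np.abs(mean - truth.as_array()), 3 * se)
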