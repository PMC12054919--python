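"""Deregression, BLUP identities, mixture-model samplers, reporting."""

import numpy as np
import pytest

from lactovar import grm as grm_mod
from lactovar import predict, syndata, varcomp
from lactovar.predict import (
    MixturePrior,
    center_genotypes,
    compare_models,
    deregress,
    gibbs_bayesr,
    gibbs_bayesrc,
    reliability,
    snp_blup,
    solve_gblup,
    solve_multiblup,
    split_reference_validation,
)
from lactovar.syndata import ClassSpec, SimConfig


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        n_individuals=400, n_variants=800, seed=23, h2_target=0.5,
        class_specs=[
            ClassSpec("qtl", 0.1, (0.3, 0.3, 0.3, 0.1)),
            ClassSpec("other", 0.0, (0.99, 0.005, 0.004, 0.001)),
        ],
    )
    g = syndata.sim_genotypes(cfg)
    cmap = syndata.sim_class_map(g, cfg)
    truth, pheno = syndata.sim_effects_and_phenotypes(g, cmap, cfg)
    G = grm_mod.compute_grm(g)
    fit = varcomp.fit_reml(pheno.y, [G])
    return g, cmap, truth, pheno, G, fit


class TestDeregress:
    @pytest.mark.parametrize(
        "pta,rel,expected", [(1.0, 1.0, 1.0), (1.0, 0.8, 1.5625), (0.0, 0.37, 0.0)]
    )
    def test_formula(self, pta, rel, expected):
        assert deregress(pta, rel) == pytest.approx(expected)

    def test_zero_reliability_rejected(self):
        with pytest.raises(ValueError):
            deregress(1.0, 0.0)


class TestGBLUP:
    def test_two_animal_closed_form(self):
        # hand-solved mixed-model equations for an explicit 2x2 G
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        y = np.array([1.0, -1.0])
        s_g, s_e = 2.0, 1.0
        V = s_g * G + s_e * np.eye(2)
        mu = float(np.ones(2) @ np.linalg.solve(V, y)) / float(
            np.ones(2) @ np.linalg.solve(V, np.ones(2))
        )
        expected = s_g * G @ np.linalg.solve(V, y - mu)
        fit = solve_gblup(y, G, s_g, s_e)
        np.testing.assert_allclose(fit.gebv, expected, atol=1e-12)

    def test_zero_genetic_variance(self, cohort):
        _, _, _, pheno, G, _ = cohort
        fit = solve_gblup(pheno.y, G, 0.0, 1.0)
        assert np.all(fit.gebv == 0)

    def test_equals_snp_blup(self, cohort):
        g, _, _, pheno, G, fit0 = cohort
        y = pheno.y
        gb = solve_gblup(y, G, fit0.components["genetic"], fit0.residual)
        W = center_genotypes(g.imputed())
        p = g.imputed().mean(axis=0) / 2
        s2b = fit0.components["genetic"] / (2 * np.sum(p * (1 - p)))
        _, gv = snp_blup(y, W, s2b, fit0.residual)
        a = gb.gebv - gb.gebv.mean()
        b = gv - gv.mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) <= 1e-6

    def test_validation_phenotypes_unused(self, cohort):
        g, _, _, pheno, G, fit0 = cohort
        y = pheno.y.copy()
        ref = np.arange(300)
        fit_a = solve_gblup(y, G, fit0.components["genetic"], fit0.residual, ref)
        y2 = y.copy()
        y2[300:] = 999.0  # perturb only validation records
        fit_b = solve_gblup(y2, G, fit0.components["genetic"], fit0.residual, ref)
        np.testing.assert_allclose(fit_a.gebv, fit_b.gebv, atol=1e-12)


class TestMultiBLUP:
    def test_zero_functional_component_reduces_to_gblup(self, cohort):
        g, cmap, _, pheno, G, fit0 = cohort
        mask = cmap.mask(g, "qtl")
        Gf = grm_mod.compute_grm(g.take_variants(mask))
        fit_m = solve_multiblup(
            pheno.y, Gf, G, 0.0, fit0.components["genetic"], fit0.residual
        )
        fit_g = solve_gblup(pheno.y, G, fit0.components["genetic"], fit0.residual)
        np.testing.assert_allclose(fit_m.gebv, fit_g.gebv, atol=1e-8)

    def test_identical_grms_sum_variances(self, cohort):
        _, _, _, pheno, G, fit0 = cohort
        s = fit0.components["genetic"]
        fit_m = solve_multiblup(pheno.y, G, G, 0.4 * s, 0.6 * s, fit0.residual)
        fit_g = solve_gblup(pheno.y, G, s, fit0.residual)
        np.testing.assert_allclose(fit_m.gebv, fit_g.gebv, atol=1e-8)


class TestGibbsSamplers:
    def test_point_mass_null_prior(self, cohort):
        g, _, _, pheno, _, _ = cohort
        W = center_genotypes(g.imputed())
        prior = MixturePrior(pi=(1.0, 0.0, 0.0, 0.0), fix_pi=True)
        fit = gibbs_bayesr(pheno.y, W, prior, n_iter=200, burn_in=50, seed=4)
        assert np.all(fit.beta_mean == 0)
        assert np.all(fit.gebv == 0)

    def test_seed_reproducibility(self, cohort):
        g, _, _, pheno, _, _ = cohort
        W = center_genotypes(g.imputed())
        a = gibbs_bayesr(pheno.y, W, n_iter=300, burn_in=100, seed=9)
        b = gibbs_bayesr(pheno.y, W, n_iter=300, burn_in=100, seed=9)
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)

    def test_ridge_limit_matches_snp_blup(self, cohort):
        g, _, _, pheno, _, fit0 = cohort
        W = center_genotypes(g.imputed())
        prior = MixturePrior(pi=(0.0, 0.0, 0.0, 1.0), fix_pi=True)
        fit = gibbs_bayesr(pheno.y, W, prior, n_iter=2000, burn_in=500, seed=5)
        p = g.imputed().mean(axis=0) / 2
        s2b = fit0.components["genetic"] / (2 * np.sum(p * (1 - p)))
        _, gv = snp_blup(pheno.y, W, s2b, fit0.residual)
        assert np.corrcoef(fit.gebv, gv)[0, 1] > 0.98

    def test_bayesrc_identical_classes_collapse(self, cohort):
        g, cmap, _, pheno, _, _ = cohort
        W = center_genotypes(g.imputed())
        pi = (0.8, 0.1, 0.07, 0.03)
        prior_r = MixturePrior(pi=pi, fix_pi=True)
        prior_rc = MixturePrior(
            pi=pi, pi_by_class={"functional": pi, "rest": pi}, fix_pi=True
        )
        mask = cmap.mask(g, "qtl")
        a = gibbs_bayesr(pheno.y, W, prior_r, n_iter=600, burn_in=200, seed=6)
        b = gibbs_bayesrc(pheno.y, W, mask, prior_rc, n_iter=600, burn_in=200, seed=6)
        # same forced prior, same seed: chains agree up to MC noise
        assert np.corrcoef(a.gebv, b.gebv)[0, 1] > 0.95

    def test_bayesrc_empty_class_falls_back(self, cohort):
        g, _, _, pheno, _, _ = cohort
        W = center_genotypes(g.imputed())
        mask = np.zeros(W.shape[1], dtype=bool)
        with pytest.warns(UserWarning):
            fit = gibbs_bayesrc(pheno.y, W, mask, n_iter=200, burn_in=50, seed=7)
        ref = gibbs_bayesr(pheno.y, W, n_iter=200, burn_in=50, seed=7)
        np.testing.assert_array_equal(fit.beta_mean, ref.beta_mean)
        assert fit.model == "BayesRC"

    def test_sigma_e_chain_stationary_after_burnin(self, cohort):
        g, _, _, pheno, _, _ = cohort
        W = center_genotypes(g.imputed())
        fit = gibbs_bayesr(pheno.y, W, n_iter=2000, burn_in=500, seed=8)
        trace = fit.mcmc["sigma2_e_trace"][500:]
        # Geweke-style z between the first 10% and last 50% of the chain
        a, b = trace[: len(trace) // 10], trace[len(trace) // 2 :]
        z = (a.mean() - b.mean()) / np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(z) < 5


class TestReporting:
    def test_reliability_trivials(self):
        x = np.random.default_rng(0).normal(size=50)
        assert reliability(x, x) == pytest.approx(100.0)
        assert reliability(2.5 * x - 1.0, x) == pytest.approx(100.0)

    def test_reliability_null_scale(self):
        rng = np.random.default_rng(1)
        vals = [
            reliability(rng.normal(size=1000), rng.normal(size=1000))
            for _ in range(50)
        ]
        # E[r^2] = 1/(n-1) under independence -> ~0.1%
        assert np.mean(vals) == pytest.approx(0.1, abs=0.05)

    def test_zero_variance_prediction(self):
        with pytest.warns(UserWarning):
            assert reliability(np.zeros(20), np.arange(20.0)) == 0.0

    def test_published_increase_rows(self):
        panel_671 = {"MY": 75.13, "MFY": 72.18, "MPY": 72.77, "MFP": 84.05, "MPP": 83.07}
        panel_625 = {"MY": 75.48, "MFY": 72.23, "MPY": 73.13, "MFP": 84.10, "MPP": 83.37}
        rep = compare_models(panel_625, panel_671, "625K", "671K")
        assert rep.rendered().loc["increase", "MY"] == pytest.approx(0.35)
        assert round(rep.mean_increase, 2) == pytest.approx(0.22)
        bayesr = {"MPP": 83.88}
        bayesrc = {"MPP": 84.56}
        assert compare_models(bayesrc, bayesr).rendered().loc[
            "increase", "MPP"
        ] == pytest.approx(0.68)

    def test_identical_reports_zero_increase(self):
        vals = {"MY": 75.0, "MPP": 83.0}
        rep = compare_models(vals, dict(vals))
        assert (rep.increases == 0).all()

    def test_trait_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"MY": 1.0}, {"MPP": 1.0})


class TestSplit:
    def test_partition_properties(self):
        years = np.array([2000, 2005, 2008, 2008, 2010, 2011])
        ref, val = split_reference_validation(np.arange(6), years, 2008)
        assert set(ref) | set(val) == set(range(6))
        assert set(ref) & set(val) == set()
        assert all(years[i] < 2008 for i in ref)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_reference_validation([1, 2], [2000, 2001], 2005)
        with pytest.raises(ValueError):
            split_reference_validation([1, 2], [2006, 2007], 2005)
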