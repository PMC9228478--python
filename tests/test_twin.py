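"""FIML twin models: closed-form oracles, grid-search oracle, invariants."""

import numpy as np
import pandas as pd
import pytest

import twinmetab as tm
from twinmetab.simulate import simulate_paired
from twinmetab.twin import (
    PairedData,
    choose_model,
    closed_form_components,
    fit_ace_ade,
    fit_saturated,
    pair_data,
    profile_ci,
    saturated_negll,
    select_covariates,
)
from conftest import balanced_paired


def _grid_saturated_oracle(paired, stages=7, n_points=9):
    """Independent grid-search ML over (mu, sigma2, cov_mz, cov_dz).

    Successive refinement around the best grid point; returns the
    correlations.  Brute force, no shared code with the fitted path.
    """
    y_all = np.concatenate([paired.mz_y.ravel(), paired.dz_y.ravel()])
    mu0, v0 = y_all.mean(), y_all.var()
    centers = np.array([mu0, v0, 0.0, 0.0])
    spans = np.array([1.0, 1.0, 0.9 * v0, 0.9 * v0])

    def negll(mu, v, cmz, cdz):
        if v <= 0 or abs(cmz) >= v or abs(cdz) >= v:
            return np.inf
        out = 0.0
        for y, c in ((paired.mz_y, cmz), (paired.dz_y, cdz)):
            det = v * v - c * c
            e1, e2 = y[:, 0] - mu, y[:, 1] - mu
            quad = (v * (e1**2 + e2**2) - 2 * c * e1 * e2) / det
            out += np.sum(np.log(2 * np.pi) + 0.5 * (np.log(det) + quad))
        return out

    for stage in range(stages):
        grids = [
            np.linspace(c - s, c + s, n_points)
            for c, s in zip(centers, spans)
        ]
        best, best_val = None, np.inf
        for mu in grids[0]:
            for v in grids[1]:
                for cmz in grids[2]:
                    for cdz in grids[3]:
                        val = negll(mu, v, cmz, cdz)
                        if val < best_val:
                            best, best_val = (mu, v, cmz, cdz), val
        centers = np.array(best)
        spans = spans * (2.0 / (n_points - 1)) * 1.2  # overlap next window
    mu, v, cmz, cdz = centers
    return cmz / v, cdz / v


class TestPairData:
    def test_complete_and_singleton_rows(self, small_cohort):
        _, (cohort, matrix, _, _) = small_cohort
        values = matrix.values.iloc[:, 0]
        paired = pair_data(values, cohort)
        n_families = cohort.family_id.nunique()
        n_used = (
            paired.n_complete["MZ"] + paired.n_complete["DZ"]
            + len(paired.single_y)
        )
        assert n_used <= n_families
        assert paired.n_obs == int(values.notna().sum())

    def test_second_multiples_rejected(self):
        cohort = pd.DataFrame(
            {
                "child_id": ["a", "b", "c"],
                "family_id": ["f1"] * 3,
                "zygosity": ["MZ"] * 3,
                "birth_order": [1, 2, 1],
                "sex": ["male"] * 3,
                "age": [8.0] * 3,
            }
        )
        with pytest.raises(ValueError):
            pair_data(pd.Series(1.0, index=["a", "b", "c"]), cohort)

    def test_twin_order_swap_leaves_likelihood_unchanged(self):
        spec = tm.SimulationSpec(
            n_mz_pairs=80, n_dz_pairs=50, n_mz_singletons=2,
            n_dz_singletons=1,
            n_metabolites={"amine": 1, "organic_acid": 0, "steroid": 0},
            var_fracs=np.array([[0.5, 0.1, 0.0, 0.4]]), seed=5,
        )
        cohort, _, _, truth = tm.simulate_cohort(spec)
        values = truth.latent.iloc[:, 0]
        swapped = cohort.assign(birth_order=3 - cohort.birth_order)
        f1 = fit_saturated(pair_data(values, cohort), ())
        f2 = fit_saturated(pair_data(values, swapped), ())
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


class TestSaturated:
    def test_matches_grid_search_oracle(self):
        paired = simulate_paired(40, 30, (0.5, 0.1, 0.0, 0.4), rng=3)
        fit = fit_saturated(paired, ())
        r_mz, r_dz = _grid_saturated_oracle(paired)
        assert fit.r_mz == pytest.approx(r_mz, abs=1e-4)
        assert fit.r_dz == pytest.approx(r_dz, abs=1e-4)

    def test_recovers_published_steroid_correlations(self):
        """Generating r_MZ=0.61, r_DZ=0.25 at the study's sample sizes."""
        # ADE parameterization reproducing those correlations exactly
        A, D = 4 * 0.25 - 0.61, 2 * 0.61 - 4 * 0.25
        paired = simulate_paired(531, 114, (A, 0.0, D, 1 - 0.61), rng=9)
        fit = fit_saturated(paired, ())
        se_mz = (1 - 0.61**2) / np.sqrt(531)
        se_dz = (1 - 0.25**2) / np.sqrt(114)
        assert abs(fit.r_mz - 0.61) < 3 * se_mz
        assert abs(fit.r_dz - 0.25) < 3 * se_dz

    def test_refuses_without_complete_pairs(self):
        paired = simulate_paired(30, 2, rng=1)
        with pytest.raises(ValueError, match="complete"):
            fit_saturated(paired, ())

    def test_singleton_deletion_changes_loglik_by_its_density(self):
        paired = simulate_paired(
            30, 20, n_mz_singletons=3, n_dz_singletons=2, rng=4
        )
        params = dict(mu=0.1, b_sex=0.0, b_age=0.0, v=1.2, cov_mz=0.6,
                      cov_dz=0.3)
        full = -saturated_negll(paired, *params.values())
        trimmed = PairedData(
            paired.mz_y, paired.mz_sex, paired.mz_age,
            paired.dz_y, paired.dz_sex, paired.dz_age,
            paired.single_y[:-1], paired.single_sex[:-1],
            paired.single_age[:-1], paired.single_is_mz[:-1],
        )
        part = -saturated_negll(trimmed, *params.values())
        y, v = paired.single_y[-1], params["v"]
        dens = -0.5 * (np.log(2 * np.pi * v) + (y - params["mu"]) ** 2 / v)
        assert full - part == pytest.approx(dens, abs=1e-10)


class TestSelectCovariates:
    def test_age_retained_sex_dropped(self):
        paired = simulate_paired(
            300, 200, (0.5, 0.1, 0.0, 0.4), beta_sex=0.0, beta_age=0.3,
            rng=12,
        )
        chosen, table = select_covariates(paired)
        assert chosen == ("age",)
        assert set(table.removed) == {"age", "sex", "age+sex"}

    def test_removal_never_increases_loglik(self):
        paired = simulate_paired(60, 40, rng=13)
        _, table = select_covariates(paired)
        assert (table.loglik_full >= table.loglik_reduced - 1e-6).all()


class TestChooseModel:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [(0.61, 0.25, "ADE"), (0.50, 0.25, "ACE"), (0.40, 0.30, "ACE")],
    )
    def test_rule(self, r_mz, r_dz, expected):
        assert choose_model(r_mz, r_dz) == expected


class TestVarianceComponents:
    def test_ade_closed_form_equivalence(self):
        paired = balanced_paired(200, 200, 1.0, 0.6, 0.2, seed=0)
        fit = fit_ace_ade(paired, "ADE", ())
        assert fit.A == pytest.approx(0.2, abs=1e-4)
        assert fit.DorC == pytest.approx(0.4, abs=1e-4)
        assert fit.E == pytest.approx(0.4, abs=1e-4)
        assert fit.h2 == pytest.approx(0.6, abs=1e-4)

    def test_ace_closed_form_equivalence(self):
        paired = balanced_paired(200, 200, 1.0, 0.5, 0.3, seed=1)
        fit = fit_ace_ade(paired, "ACE", ())
        assert fit.A == pytest.approx(0.4, abs=1e-4)
        assert fit.DorC == pytest.approx(0.1, abs=1e-4)
        assert fit.E == pytest.approx(0.5, abs=1e-4)

    def test_no_familial_resemblance_gives_pure_e(self):
        paired = balanced_paired(150, 150, 1.0, 0.0, 0.0, seed=2)
        for model in ("ADE", "ACE"):
            fit = fit_ace_ade(paired, model, ())
            assert fit.A == pytest.approx(0.0, abs=1e-3)
            assert fit.DorC == pytest.approx(0.0, abs=1e-3)
            assert fit.E == pytest.approx(1.0, abs=1e-3)

    def test_broad_h2_equals_fitted_mz_correlation(self):
        """On complete data the ADE fit reproduces r_MZ as (A+D)/V."""
        paired = balanced_paired(120, 80, 1.3, 0.7, 0.25, seed=3)
        sat = fit_saturated(paired, ())
        fit = fit_ace_ade(paired, "ADE", ())
        assert fit.h2 == pytest.approx(sat.r_mz, abs=1e-4)

    def test_negative_components_allowed(self):
        # r_mz > 4 r_dz forces a negative additive component in ADE
        paired = balanced_paired(300, 150, 1.0, 0.6, 0.1, seed=4)
        fit = fit_ace_ade(paired, "ADE", ())
        expected = closed_form_components("ADE", 1.0, 0.6, 0.1)
        assert fit.A == pytest.approx(expected[0], abs=1e-4)
        assert fit.A < 0
        assert fit.h2 == pytest.approx(0.6, abs=1e-4)

    def test_nested_in_saturated(self):
        paired = simulate_paired(100, 60, (0.4, 0.0, 0.2, 0.4), rng=6)
        sat = fit_saturated(paired, ())
        for model in ("ADE", "ACE"):
            fit = fit_ace_ade(paired, model, ())
            assert fit.loglik <= sat.loglik + 1e-6


class TestProfileCI:
    def test_interval_contains_estimate_and_shrinks_with_n(self):
        widths = []
        for n_mz, n_dz, seed in [(250, 120, 0), (2500, 1200, 0)]:
            paired = simulate_paired(n_mz, n_dz, (0.5, 0.1, 0.0, 0.4),
                                     rng=seed)
            fit = fit_ace_ade(paired, "ACE", ())
            lo, hi = profile_ci(paired, fit, "a2")
            assert lo < fit.a2 < hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_h2_interval_brackets_truth_at_study_size(self):
        paired = simulate_paired(531, 114, (0.3, 0.0, 0.3, 0.4), rng=8)
        fit = fit_ace_ade(paired, "ADE", ())
        lo, hi = profile_ci(paired, fit, "h2")
        assert lo < 0.6 < hi


class TestPipeline:
    def test_regime_recovery_and_skip_logging(self, caplog):
        """Strongly separated ADE/ACE regimes are recovered; an all-missing
        metabolite is skipped, not fatal."""
        n_ade, n_ace = 6, 3
        vf = np.array(
            [[0.2, 0.0, 0.4, 0.4]] * n_ade + [[0.3, 0.3, 0.0, 0.4]] * n_ace
        )
        spec = tm.SimulationSpec(
            n_mz_pairs=600, n_dz_pairs=400, n_mz_singletons=0,
            n_dz_singletons=0,
            n_metabolites={"amine": n_ade + n_ace, "organic_acid": 0,
                           "steroid": 0},
            var_fracs=vf, beta_sex=0.0, beta_age=0.0, seed=21,
        )
        cohort, matrix, _, truth = tm.simulate_cohort(spec)
        processed = truth.latent.copy()
        processed["dead"] = np.nan
        results = tm.run_twin_pipeline(processed, cohort, compute_ci=False)
        assert "dead" not in set(results.metabolite)
        assert "skipped" in caplog.text
        models = results.set_index("metabolite").model
        assert (models.iloc[:n_ade] == "ADE").mean() >= 0.8
        assert (models.iloc[n_ade:] == "ACE").mean() >= 0.6
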