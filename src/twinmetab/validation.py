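"""Replicate-based validation studies: oracle agreement and calibration.

Monte-Carlo studies exercising the estimators under known truth: exact
closed-form equivalence of the FIML variance-component fits on
moment-matched data, parameter recovery and profile-CI coverage at the
study's sample sizes, type-I error of the covariate LRTs and of the
association-scan Wald tests, and false-discovery control of the BH-FDR
scan under a global null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import association
from .lmm import fit_random_intercept_lmm
from .simulate import (
    SimulationSpec,
    _latent_components,
    _simulate_families,
    exact_moment_pairs,
    simulate_paired,
)
from .twin import (
    PairedData,
    closed_form_components,
    fit_ace_ade,
    fit_saturated,
    profile_ci,
    select_covariates,
)


def _spawn(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(k + 1)[k])


def closed_form_agreement(
    n_metabolites: int = 20,
    n_mz: int = 200,
    n_dz: int = 200,
    seed: int = 0,
) -> dict:
    """FIML vs 3-moment closed form on moment-matched complete pairs.

    Draws a panel of (cov_MZ, cov_DZ) targets, builds data whose ML sample
    moments equal them exactly, and compares the FIML ADE and ACE component
    estimates with the closed-form solutions, plus broad-sense h2 against
    the fitted MZ correlation.
    """
    rng = np.random.default_rng(seed)
    max_diff = {"ADE": 0.0, "ACE": 0.0}
    max_h2_vs_rmz = 0.0
    for _ in range(n_metabolites):
        v = rng.uniform(0.8, 1.3)
        cov_mz = v * rng.uniform(0.3, 0.75)
        cov_dz = cov_mz * rng.uniform(0.3, 0.7)
        mz = exact_moment_pairs(n_mz, v, cov_mz, rng)
        dz = exact_moment_pairs(n_dz, v, cov_dz, rng)
        paired = PairedData(
            mz, np.zeros((n_mz, 2)), np.zeros(n_mz),
            dz, np.zeros((n_dz, 2)), np.zeros(n_dz),
            np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool),
        )
        sat = fit_saturated(paired, ())
        for model in ("ADE", "ACE"):
            fit = fit_ace_ade(paired, model, ())
            expect = closed_form_components(model, v, cov_mz, cov_dz)
            diff = max(
                abs(fit.A - expect[0]),
                abs(fit.DorC - expect[1]),
                abs(fit.E - expect[2]),
            )
            max_diff[model] = max(max_diff[model], diff)
            if model == "ADE":
                max_h2_vs_rmz = max(max_h2_vs_rmz, abs(fit.h2 - sat.r_mz))
    return {
        "ade_max_abs_diff": max_diff["ADE"],
        "ace_max_abs_diff": max_diff["ACE"],
        "h2_vs_rmz_max_abs_diff": max_h2_vs_rmz,
        "n": n_metabolites,
    }


def parameter_recovery_study(
    n_reps: int = 200,
    n_mz: int = 531,
    n_dz: int = 114,
    var_fracs: tuple = (0.5, 0.1, 0.0, 0.4),
    ci_level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Bias of standardized ACE shares and profile-CI coverage for a2.

    Simulates complete twin pairs at the requested sizes with known
    (A, C, E) and refits; reports the mean absolute bias of the three
    standardized shares and the empirical coverage of the a2 profile
    interval.
    """
    rng = _spawn(seed, 0)
    A, C, D, E = var_fracs
    truth = np.array([A, C, E])
    biases, covered = [], []
    for _ in range(n_reps):
        paired = simulate_paired(n_mz, n_dz, var_fracs, rng=rng)
        fit = fit_ace_ade(paired, "ACE", ())
        biases.append(np.array([fit.a2, fit.dc2, fit.e2]) - truth)
        lo, hi = profile_ci(paired, fit, "a2", level=ci_level)
        covered.append(lo <= A <= hi)
    biases = np.array(biases)
    mean_abs_bias = np.abs(biases.mean(axis=0))
    return {
        "mean_abs_bias_a2": float(mean_abs_bias[0]),
        "mean_abs_bias_c2": float(mean_abs_bias[1]),
        "mean_abs_bias_e2": float(mean_abs_bias[2]),
        "max_mean_abs_bias": float(mean_abs_bias.max()),
        "a2_ci_coverage": float(np.mean(covered)),
        "n": n_reps,
    }


def lrt_type1_study(
    n_reps: int = 200,
    n_mz: int = 531,
    n_dz: int = 114,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the covariate-removal LRTs when both betas are 0."""
    rng = _spawn(seed, 1)
    reject_age, reject_sex = [], []
    for _ in range(n_reps):
        paired = simulate_paired(
            n_mz, n_dz, (0.5, 0.1, 0.0, 0.4), beta_sex=0.0, beta_age=0.0,
            rng=rng,
        )
        chosen, _ = select_covariates(paired, alpha=alpha)
        reject_age.append("age" in chosen)
        reject_sex.append("sex" in chosen)
    rate_age = float(np.mean(reject_age))
    rate_sex = float(np.mean(reject_sex))
    return {
        "type1_age": rate_age,
        "type1_sex": rate_sex,
        "type1_pooled": float(np.mean(reject_age + reject_sex)),
        "n": n_reps,
    }


def wald_type1_study(
    n_reps: int = 200,
    n_clusters: int = 600,
    tau2: float = 0.3,
    sigma2: float = 0.7,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the LMM Wald z-test for a null age effect."""
    rng = _spawn(seed, 2)
    cluster = np.repeat(np.arange(n_clusters), 2)
    rejections = []
    for _ in range(n_reps):
        age = np.repeat(rng.uniform(5.7, 12.9, n_clusters), 2)
        u = np.repeat(rng.normal(0, np.sqrt(tau2), n_clusters), 2)
        y = u + rng.normal(0, np.sqrt(sigma2), 2 * n_clusters)
        X = np.column_stack([np.ones_like(age), age])
        fit = fit_random_intercept_lmm(y, X, cluster)
        rejections.append(fit.p_values[1] < alpha)
    return {"type1_wald_age": float(np.mean(rejections)), "n": n_reps}


def fdr_null_study(
    n_reps: int = 200,
    n_metabolites: int = 86,
    q: float = 0.05,
    seed: int = 0,
) -> dict:
    """Mean false-discovery proportion of the null 86-metabolite scan.

    Every metabolite is null (no sex or age effect) but carries family
    clustering; the scan is the full sex+age analysis with BH-FDR at
    q <= 0.05.  Under a global null every discovery is false, so within
    each term family (the unit the correction controls) the FDP is 1 when
    anything is called and 0 otherwise.

    The null is simulated from the scan's own model class: a single
    family-level correlation shared by MZ and DZ pairs (shared-environment
    structure), since FDR control presupposes valid p-values.  Robustness
    to zygosity-dependent clustering is a separate question (see the
    methods note).
    """
    rng = _spawn(seed, 3)
    spec = SimulationSpec(
        n_metabolites={"amine": n_metabolites, "organic_acid": 0, "steroid": 0},
        var_fracs=np.tile([0.0, 0.5, 0.0, 0.5], (n_metabolites, 1)),
        beta_sex=0.0,
        beta_age=0.0,
        seed=seed,
    )
    cohort = _simulate_families(spec, rng)
    fdps = []
    for _ in range(n_reps):
        latent, _ = _latent_components(spec, cohort, rng)
        processed = pd.DataFrame(
            latent,
            index=cohort["child_id"].to_numpy(),
            columns=[f"am{j:03d}" for j in range(n_metabolites)],
        )
        table = association.run_association_scan(
            processed, cohort, "sex_age_continuous", q_threshold=q
        )
        for _, term_table in table.groupby("term"):
            fdps.append(float(term_table["significant"].any()))
    return {"mean_fdp": float(np.mean(fdps)), "n": n_reps}
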