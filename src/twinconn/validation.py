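"""Simulation studies validating the pipeline against known ground truth.

Each study generates data with the synthetic-cohort module at the study's
sample size (123 MZ + 67 DZ pairs unless stated), runs the corresponding
analysis stage, and summarises recovery/calibration.  These functions back
both the acceptance test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gradient, hierarchy, screening, simulate
from .heritability import fit_ae, inverse_normal
from .simulate import design_matrix

STUDY_N_MZ = 123
STUDY_N_DZ = 67

#: Covariate effect sizes used when a study includes fixed effects.
STUDY_COVARIATE_EFFECTS = {"age": 0.02, "sex": 0.3, "mean_fd": -0.5}


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def h2_recovery_study(
    levels=(0.2, 0.4, 0.6, 0.8),
    n_rep: int = 200,
    n_mz: int = STUDY_N_MZ,
    n_dz: int = STUDY_N_DZ,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias and CI coverage of the AE estimator across true h2 levels.

    Per level: ``n_rep`` cohorts with covariate effects; returns mean_h2,
    bias, and empirical coverage of the 95% profile-likelihood interval.
    """
    seeds = _child_seeds(seed, 2 * n_rep * len(levels)).reshape(len(levels), n_rep, 2)
    rows = []
    for li, h2 in enumerate(levels):
        est = np.empty(n_rep)
        covered = np.empty(n_rep, dtype=bool)
        for r in range(n_rep):
            coh = simulate.generate_pedigree(n_mz, n_dz, seed=int(seeds[li, r, 0]))
            y = simulate.generate_phenotype(
                coh, h2, covariate_effects=STUDY_COVARIATE_EFFECTS,
                seed=int(seeds[li, r, 1]),
            )
            res = fit_ae(y, design_matrix(coh), coh)
            est[r] = res.h2
            covered[r] = res.ci_low <= h2 <= res.ci_high
        rows.append(
            {"h2_true": h2, "mean_h2": est.mean(), "bias": est.mean() - h2,
             "sd": est.std(ddof=1), "coverage": covered.mean(), "n_rep": n_rep}
        )
    return pd.DataFrame(rows)


def lrt_null_study(
    n_rep: int = 1000,
    n_mz: int = STUDY_N_MZ,
    n_dz: int = STUDY_N_DZ,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Calibration of the mixture LRT at h2_true = 0.

    Returns the rejection rate at ``alpha`` and the fraction of replicates
    with the statistic on the boundary point mass (expected ~ 0.5).
    """
    seeds = _child_seeds(seed, 2 * n_rep).reshape(n_rep, 2)
    p = np.empty(n_rep)
    at_zero = np.empty(n_rep, dtype=bool)
    for r in range(n_rep):
        coh = simulate.generate_pedigree(n_mz, n_dz, seed=int(seeds[r, 0]))
        y = simulate.generate_phenotype(coh, 0.0, seed=int(seeds[r, 1]))
        res = fit_ae(y, design_matrix(coh), coh)
        p[r] = res.p_mixture
        at_zero[r] = res.lrt_stat <= 1e-8
    return {
        "rejection_rate": float(np.mean(p <= alpha)),
        "point_mass_rate": float(at_zero.mean()),
        "n_rep": n_rep,
    }


def blockperm_null_study(
    n_rep: int = 500,
    n_perm: int = 199,
    n_mz: int = STUDY_N_MZ,
    n_dz: int = STUDY_N_DZ,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the family-block sign-flip test under an i.i.d. null."""
    rng = np.random.default_rng(seed)
    coh = simulate.generate_pedigree(n_mz, n_dz, seed=int(rng.integers(2**31)))
    p = np.empty(n_rep)
    for r in range(n_rep):  # independent data and flip draws per replicate
        z = rng.standard_normal((len(coh), 1))
        p[r] = screening.block_permutation_test(
            z, coh, n_perm=n_perm, seed=int(rng.integers(2**31))
        )[0]
    return {"rejection_rate": float(np.mean(p <= alpha)), "n_rep": n_rep}


_RECOVERY_TRUTH = simulate.PlasticityCurve(a1=0.25, b1=0.8, a2=0.001, b2=0.6)


def two_component_recovery_study(
    n_seeds: int = 100, noise_sd: float = 0.03, seed: int = 0
) -> dict:
    """Noiseless and noisy round-trip recovery of the plasticity curve.

    The noiseless fit must return the generative parameters; under additive
    Gaussian noise the fitted curve's RMSE against the true curve is
    summarised relative to the noise level.
    """
    eta = np.repeat(np.arange(11.0), 2)  # two areas per level, eta 0..10
    truth = _RECOVERY_TRUTH
    y0 = truth.h2(eta)
    clean = gradient.fit_two_component(eta, y0, h_max=truth.h_max)
    param_err = np.max(np.abs(
        np.array([clean.a1_, clean.b1_, clean.a2_, clean.b2_])
        - np.array([truth.a1, truth.b1, truth.a2, truth.b2])
    ))
    rng = np.random.default_rng(seed)
    rmses = []
    for _ in range(n_seeds):
        y = y0 + noise_sd * rng.standard_normal(len(eta))
        m = gradient.fit_two_component(eta, y, h_max=truth.h_max)
        if m.converged_:
            rmses.append(float(np.sqrt(np.mean((m.predict(eta) - y0) ** 2))))
    return {
        "noiseless_max_param_error": float(param_err),
        "noiseless_r2": float(clean.r2_),
        "median_curve_rmse": float(np.median(rmses)),
        "rmse_noise_ratio": float(np.median(rmses) / noise_sd),
        "n_converged": len(rmses),
        "n_seeds": n_seeds,
    }


def component_selection_study(
    n_rep: int = 200, noise_sd: float = 0.03, seed: int = 0
) -> dict:
    """Akaike-weight selection between the frozen short/long components.

    Targets generated from the short component (ICC-like, increasing with
    level) and from the long component (anatomy-like, decreasing) with
    additive noise; reports how often the correct component wins.
    """
    eta = np.repeat(np.arange(11.0), 2)
    truth = _RECOVERY_TRUTH
    full = gradient.fit_two_component(eta, truth.h2(eta), h_max=truth.h_max)
    rng = np.random.default_rng(seed)
    wins = {"short": 0, "long": 0}
    for which, base in (("short", 0.6 - full.short_term(eta)),
                        ("long", 0.8 - full.long_term(eta))):
        for _ in range(n_rep):
            y = base + noise_sd * rng.standard_normal(len(eta))
            _, aic_s, _ = gradient.component_intercept_fit(eta, y, full, "short")
            _, aic_l, _ = gradient.component_intercept_fit(eta, y, full, "long")
            w = gradient.akaike_weights([aic_s, aic_l])
            winner = "short" if w[0] > 0.5 else "long"
            wins[which] += winner == which
    return {
        "short_correct_rate": wins["short"] / n_rep,
        "long_correct_rate": wins["long"] / n_rep,
        "n_rep": n_rep,
    }


def end_to_end_run(
    truth,
    seed: int,
    n_mz: int = STUDY_N_MZ,
    n_dz: int = STUDY_N_DZ,
    n_perm: int = 250,
    q_fdr: float = 0.05,
    covariates=("age", "sex", "mean_fd", "recon_version"),
) -> dict:
    """One full synthetic analysis on the 24-area single-hemisphere graph.

    Generates per-subject connection tables with connection-level true h2
    derived from ``truth`` (a curve object with an ``h2`` method), screens
    connections by family-block permutation + BH-FDR, estimates AE
    heritability per kept connection (inverse-normal transformed, with
    covariates), averages per area and fits the gradient models.
    """
    rng = np.random.default_rng(seed)
    edges = simulate.visual_area_graph(("L",))
    levels = hierarchy.levels_table(edges, roots=("L_V1",)).set_index("area")["eta"]
    conn_truth = simulate.connection_h2_from_levels(levels, truth)
    coh = simulate.generate_pedigree(n_mz, n_dz, seed=int(rng.integers(2**31)))
    mean_z = rng.normal(0.30, 0.05, size=len(conn_truth))
    z = simulate.generate_phenotypes(
        coh, conn_truth.to_numpy(), mean=mean_z, total_var=0.02,
        covariate_effects={"mean_fd": -0.05}, seed=int(rng.integers(2**31)),
    )
    p_raw = screening.block_permutation_test(
        z, coh, n_perm=n_perm, seed=int(rng.integers(2**31))
    )
    keep = screening.bh_fdr(p_raw, q=q_fdr)["keep"].to_numpy()

    x = design_matrix(coh, covariates)
    h2_est = np.full(len(conn_truth), np.nan)
    for k in np.flatnonzero(keep):
        h2_est[k] = fit_ae(inverse_normal(z[:, k]), x, coh).h2
    h2_series = pd.Series(h2_est[keep], index=conn_truth.index[keep])
    profile = gradient.area_profile(h2_series)
    eta = levels.loc[profile["area"]].to_numpy(dtype=float)
    y = profile["mean"].to_numpy()
    fit_lin = gradient.fit_polynomial(eta, y, 1)
    fit_quad = gradient.fit_polynomial(eta, y, 2)
    f, _, _, p_nested = gradient.nested_f_test(fit_lin, fit_quad)
    return {
        "n_kept": int(keep.sum()),
        "n_connections": len(conn_truth),
        "profile": profile.assign(eta=eta),
        "linear": fit_lin,
        "quadratic": fit_quad,
        "nested_f": f,
        "nested_p": p_nested,
        "levels": levels,
    }


def curvature_detection_study(
    n_runs: int = 50, seed: int = 0, alpha: float = 0.05, **kwargs
) -> dict:
    """Nested-F detection of the generative curvature, end to end.

    Under the non-monotonic two-component truth the quadratic model should
    beat the linear model nearly always; under a monotone-linear truth the
    rejection rate should stay near ``alpha``.
    """
    seeds = _child_seeds(seed, 2 * n_runs).reshape(2, n_runs)
    out = {}
    for name, truth, row in (
        ("two_component", simulate.PlasticityCurve(), 0),
        ("linear", simulate.LinearProfile(), 1),
    ):
        rejections = 0
        for r in range(n_runs):
            run = end_to_end_run(truth, seed=int(seeds[row, r]), **kwargs)
            rejections += run["nested_p"] <= alpha
        out[f"{name}_rejection_rate"] = rejections / n_runs
    out["n_runs"] = n_runs
    return out
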