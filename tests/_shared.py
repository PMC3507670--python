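"""Shared heavyweight simulation runs, cached so the unit suite and the
acceptance suite reuse the same replicates."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

import misstrial as mt

# Reduced replicate count (documented): full-scale criterion is 50.
N_REPS = 20
N_COHORT = 20000


def single_attempt_config(n: int, beta2: float) -> mt.CohortConfig:
    """Everyone receives exactly one phone attempt and no email, so the
    attempt process coincides with the single-shot selection model."""
    cfg = mt.default_iquit_config(n=n, beta2=beta2)
    pmf = np.zeros(10)
    pmf[0] = 1.0
    cfg.call_budget_pmf = pmf
    cfg.email_availability = 0.0
    return cfg


def selection_truth(cfg: mt.CohortConfig) -> mt.SelectionParams:
    ap = cfg.attempt_params
    return mt.SelectionParams(
        alpha0=cfg.alpha0,
        alpha1=cfg.alpha1,
        beta0=float(ap.beta0_m[0]),
        beta1=ap.beta1,
        beta2=ap.beta2,
    )


@lru_cache(maxsize=None)
def selection_recovery(beta2_true: float = -1.0, n_reps: int = N_REPS, n: int = N_COHORT):
    """Fit the selection model at the true fixed beta2 on self-generated
    single-attempt cohorts; per replicate, record |estimate-truth|/SE for
    every free parameter."""
    cfg = single_attempt_config(n, beta2_true)
    truth = selection_truth(cfg)
    truth_vec = truth.to_vector()
    out = []
    for rep in range(n_reps):
        records, _ = mt.generate_cohort(cfg, seed=1000 + rep)
        fit = mt.fit_fixed_beta2(records, beta2_true)
        z = np.abs(fit.estimates - truth_vec) / fit.se
        out.append(
            {"converged": fit.converged, "names": fit.names,
             "z": z, "se_defined": fit.se_defined}
        )
    return out


@lru_cache(maxsize=None)
def selection_full_mnar_coverage(beta2_true: float = 1.5, n_reps: int = N_REPS, n: int = N_COHORT):
    """Wald-CI coverage of beta2 from the full joint selection fit on
    correctly specified single-attempt cohorts."""
    cfg = single_attempt_config(n, beta2_true)
    out = []
    for rep in range(n_reps):
        records, _ = mt.generate_cohort(cfg, seed=2000 + rep)
        fit = mt.fit_full_mnar(records)
        lo, hi = fit.wald_ci("beta2")
        out.append(
            {"converged": fit.converged, "covered": bool(lo <= beta2_true <= hi),
             "beta2": fit.estimate("beta2"), "se": fit.se_of("beta2")}
        )
    return out


@lru_cache(maxsize=None)
def attempts_beta2_bias(beta2_true: float = 0.2, n_reps: int = 50, n: int = 1758):
    """beta2 estimates from MNAR attempts fits at trial scale, for the
    zero-bias invariant check."""
    cfg = mt.default_iquit_config(n=n, beta2=beta2_true)
    est = []
    for rep in range(n_reps):
        records, _ = mt.generate_cohort(cfg, seed=4000 + rep)
        fit = mt.fit_mnar_attempts(records)
        if fit.converged:
            est.append(fit.estimate("beta2"))
    return np.array(est)


@lru_cache(maxsize=None)
def attempts_recovery(beta2_true: float = 0.2, n_reps: int = N_REPS, n: int = N_COHORT):
    """Joint MNAR fit of the attempts model on self-generated cohorts from
    the default multi-attempt process; records per-parameter z-scores and
    beta2 CI coverage."""
    cfg = mt.default_iquit_config(n=n, beta2=beta2_true)
    ap = cfg.attempt_params
    out = []
    for rep in range(n_reps):
        records, _ = mt.generate_cohort(cfg, seed=3000 + rep)
        fit = mt.fit_mnar_attempts(records)
        truth = {"alpha0": ap.alpha0, "beta2": ap.beta2}
        for name, v in zip(mt.core_data.COVARIATES, ap.alpha1):
            truth[f"alpha1_{name}"] = v
        for name, v in zip(mt.core_data.COVARIATES, ap.beta1):
            truth[f"beta1_{name}"] = v
        for m in range(1, 11):
            truth[f"beta0_{m}"] = ap.beta0_m[m - 1]
        truth["beta0_email"] = ap.beta0_m[10]
        truth_vec = np.array([truth[nm] for nm in fit.names])
        z = np.abs(fit.estimates - truth_vec) / fit.se
        lo, hi = fit.wald_ci("beta2")
        out.append(
            {"converged": fit.converged, "names": fit.names, "z": z,
             "covered": bool(lo <= beta2_true <= hi),
             "beta2": fit.estimate("beta2"), "se": fit.se_of("beta2")}
        )
    return out
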