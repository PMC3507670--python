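"""Attempt-level model of nonresponse for a possibly-MNAR binary outcome.

Each contact attempt m (phone calls 1..10; a final email attempt indexed 11
regardless of the number of calls that preceded it) has its own intercept,
while covariate and outcome effects are shared across attempts:

    logit P(R'_m = 1 | Y=y, x) = beta0_m + beta1' x + beta2 * y

This is a discrete-time hazard / stratified logistic model that also handles
unobserved outcomes: the full likelihood has four branches (phone responder,
email responder, email nonresponder, phone-only nonresponder), with the
outcome summed out for nonresponders and empty failure products equal to one.
If every participant receives exactly one attempt the model reduces to the
single-shot selection model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, log_expit
from scipy.stats import chi2

from ._optim import (
    FitResult,
    Standardizer,
    maximize_loglik,
    observed_information,
    se_from_information,
)
from .core_data import (
    COVARIATES,
    EMAIL_ATTEMPT,
    SMOKING_RELATED,
    AttemptSummaryTable,
    ParticipantRecord,
)
from .exceptions import DataValidationError, DegenerateDataError
from .selection import _logit_fit

logger = logging.getLogger(__name__)

N_ATTEMPTS = EMAIL_ATTEMPT  # 10 phone attempts + email


@dataclass
class AttemptParams:
    """Parameters of the joint outcome / attempt-success model.

    ``beta0_m`` holds the 11 per-attempt intercepts (index 10 = email); NaN
    entries mark attempts absent from the data whose intercepts were dropped.
    ``gamma_email_calls`` is the optional coefficient of the phone-call count
    in the email attempt's linear predictor (robustness variant; 0 = off).
    """

    alpha0: float
    alpha1: np.ndarray
    beta0_m: np.ndarray
    beta1: np.ndarray
    beta2: float = 0.0
    gamma_email_calls: float = 0.0

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta0_m = np.asarray(self.beta0_m, dtype=float)
        if self.beta0_m.shape != (N_ATTEMPTS,):
            raise DataValidationError(f"beta0_m must have length {N_ATTEMPTS}")
        if self.alpha1.shape != self.beta1.shape or self.alpha1.ndim != 1:
            raise DataValidationError("alpha1 and beta1 must be 1-d vectors of equal length")
        for v in (self.alpha0, self.beta2, self.gamma_email_calls):
            if not np.isfinite(v):
                raise DataValidationError("attempt parameters must be finite")
        if not (np.all(np.isfinite(self.alpha1)) and np.all(np.isfinite(self.beta1))):
            raise DataValidationError("attempt parameters must be finite")

    @property
    def k(self) -> int:
        return self.alpha1.size


@dataclass(frozen=True)
class RobustnessSpec:
    """One row of the robustness harness: a covariate subset, a participant
    filter, and whether the email attempt's success may depend on the number
    of failed phone calls."""

    label: str
    covariates: str = "all"  # all | smoking | non_smoking | none | all_except_sex
    participants: str = "all"  # all | age_le_median | age_gt_median | men | women | max5calls
    email_depends_on_calls: bool = False


def default_robustness_specs() -> list[RobustnessSpec]:
    return [
        RobustnessSpec("smoking-related covariates", covariates="smoking"),
        RobustnessSpec("non-smoking-related covariates", covariates="non_smoking"),
        RobustnessSpec("no covariates", covariates="none"),
        RobustnessSpec("younger (age <= median)", participants="age_le_median"),
        RobustnessSpec("older (age > median)", participants="age_gt_median"),
        RobustnessSpec("men", covariates="all_except_sex", participants="men"),
        RobustnessSpec("women", covariates="all_except_sex", participants="women"),
        RobustnessSpec("5 calls or fewer", participants="max5calls"),
        RobustnessSpec("email depends on calls", email_depends_on_calls=True),
    ]


@dataclass(frozen=True)
class AttemptData:
    """Array view of a cohort for the attempt-level likelihood."""

    X: np.ndarray
    y: np.ndarray  # -1 where missing
    r: np.ndarray
    t: np.ndarray
    email: np.ndarray  # bool
    succ: np.ndarray  # 0 = none, 1..11 otherwise
    names: tuple[str, ...] = COVARIATES

    @classmethod
    def from_records(cls, records: Sequence[ParticipantRecord]) -> "AttemptData":
        if len(records) == 0:
            raise DataValidationError("empty cohort")
        return cls(
            X=np.stack([rec.x for rec in records]),
            y=np.array([-1 if rec.y is None else rec.y for rec in records], dtype=int),
            r=np.array([rec.r for rec in records], dtype=int),
            t=np.array([rec.attempts.t for rec in records], dtype=int),
            email=np.array([rec.attempts.email_attempted for rec in records], dtype=bool),
            succ=np.array(
                [rec.attempts.success_attempt or 0 for rec in records], dtype=int
            ),
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, mask: np.ndarray) -> "AttemptData":
        return AttemptData(
            X=self.X[mask], y=self.y[mask], r=self.r[mask], t=self.t[mask],
            email=self.email[mask], succ=self.succ[mask], names=self.names,
        )

    def select_covariates(self, keep: Sequence[str]) -> "AttemptData":
        idx = [self.names.index(c) for c in keep]
        return replace(self, X=self.X[:, idx], names=tuple(keep))


def _as_data(records: Union[AttemptData, Sequence[ParticipantRecord]]) -> AttemptData:
    return records if isinstance(records, AttemptData) else AttemptData.from_records(records)


@dataclass(frozen=True)
class _Expansion:
    """One row per attempt made: participant index, attempt index, success."""

    ridx: np.ndarray
    m: np.ndarray
    s: np.ndarray
    present: np.ndarray  # sorted unique attempt indices in the data
    pos: np.ndarray  # position of each row's attempt in `present`

    @classmethod
    def build(cls, data: AttemptData) -> "_Expansion":
        ridx, m, s = [], [], []
        for i in range(data.n):
            for j in range(1, data.t[i] + 1):
                ridx.append(i)
                m.append(j)
                s.append(1 if data.succ[i] == j else 0)
            if data.email[i]:
                ridx.append(i)
                m.append(EMAIL_ATTEMPT)
                s.append(1 if data.succ[i] == EMAIL_ATTEMPT else 0)
        m = np.array(m, dtype=int)
        present = np.unique(m)
        lookup = {v: p for p, v in enumerate(present)}
        pos = np.array([lookup[v] for v in m], dtype=int)
        return cls(
            ridx=np.array(ridx, dtype=int), m=m, s=np.array(s, dtype=int),
            present=present, pos=pos,
        )


def attempt_probability(
    params: AttemptParams, m: int, x: np.ndarray, y, t: Optional[int] = None
) -> np.ndarray:
    """Success probability of attempt ``m`` given outcome ``y`` and
    covariates ``x``; ``t`` (phone-call count) only enters for the email
    attempt when the email-depends-on-calls variant is active."""
    if not 1 <= m <= N_ATTEMPTS:
        raise DataValidationError(f"attempt index {m} outside 1..{N_ATTEMPTS}")
    x = np.asarray(x, dtype=float)
    eta = params.beta0_m[m - 1] + x @ params.beta1 + params.beta2 * np.asarray(y)
    if m == EMAIL_ATTEMPT and params.gamma_email_calls != 0.0:
        if t is None:
            raise DataValidationError("phone-call count t required for the email variant")
        eta = eta + params.gamma_email_calls * t
    return expit(eta)


def _theta_from_params(params: AttemptParams, exp: _Expansion, gamma: bool) -> np.ndarray:
    b0 = params.beta0_m[exp.present - 1]
    if not np.all(np.isfinite(b0)):
        raise DataValidationError("beta0_m undefined (NaN) for an attempt present in the data")
    theta = np.concatenate([[params.alpha0], params.alpha1, b0, params.beta1, [params.beta2]])
    if gamma:
        theta = np.concatenate([theta, [params.gamma_email_calls]])
    return theta


def _loglik_grad(
    theta: np.ndarray, data: AttemptData, exp: _Expansion, gamma: bool
):
    """Full attempt-level log-likelihood and analytic gradient.

    Layout: [alpha0, alpha1 (k), beta0 at present attempts, beta1 (k),
    beta2, (gamma_email_calls)].
    """
    k = data.k
    n_m = exp.present.size
    a0, a1 = theta[0], theta[1 : 1 + k]
    b0 = theta[1 + k : 1 + k + n_m]
    b1 = theta[1 + k + n_m : 1 + 2 * k + n_m]
    b2 = theta[1 + 2 * k + n_m]
    g_email = theta[1 + 2 * k + n_m + 1] if gamma else 0.0

    a_lin = a0 + data.X @ a1
    xb = data.X @ b1
    is_email_row = exp.m == EMAIL_ATTEMPT
    tcol = np.where(is_email_row, data.t[exp.ridx], 0).astype(float)
    base_row = b0[exp.pos] + xb[exp.ridx] + g_email * tcol

    grad = np.zeros_like(theta)
    ll = 0.0
    resp_row = data.r[exp.ridx] == 1

    # --- responders: outcome observed, per-attempt Bernoulli terms
    if resp_row.any():
        rr = exp.ridx[resp_row]
        y_row = data.y[rr].astype(float)
        eta = base_row[resp_row] + b2 * y_row
        s = exp.s[resp_row].astype(float)
        ll += float(np.sum(log_expit(np.where(s == 1, eta, -eta))))
        w = s - expit(eta)
        grad[1 + k : 1 + k + n_m] += np.bincount(exp.pos[resp_row], weights=w, minlength=n_m)
        grad[1 + k + n_m : 1 + 2 * k + n_m] += data.X[rr].T @ w
        grad[1 + 2 * k + n_m] += float(w @ y_row)
        if gamma:
            grad[-1] += float(w @ tcol[resp_row])

    resp_p = data.r == 1
    if resp_p.any():
        yr = data.y[resp_p].astype(float)
        al = a_lin[resp_p]
        ll += float(np.sum(log_expit(np.where(yr == 1, al, -al))))
        wa = yr - expit(al)
        grad[0] += wa.sum()
        grad[1 : 1 + k] += data.X[resp_p].T @ wa

    # --- nonresponders: every attempt failed; outcome summed out
    nonr_p = ~resp_p
    if nonr_p.any():
        nr_ids = np.flatnonzero(nonr_p)
        local = -np.ones(data.n, dtype=int)
        local[nr_ids] = np.arange(nr_ids.size)
        nr_row = ~resp_row
        rl = local[exp.ridx[nr_row]]
        eta0 = base_row[nr_row]
        eta1 = eta0 + b2
        f0 = np.bincount(rl, weights=log_expit(-eta0), minlength=nr_ids.size)
        f1 = np.bincount(rl, weights=log_expit(-eta1), minlength=nr_ids.size)
        al = a_lin[nr_ids]
        l1 = log_expit(al) + f1
        l0 = log_expit(-al) + f0
        lse = np.logaddexp(l1, l0)
        ll += float(lse.sum())
        w1 = np.exp(l1 - lse)  # posterior P(Y=1 | all attempts failed)
        wa = w1 - expit(al)
        grad[0] += wa.sum()
        grad[1 : 1 + k] += data.X[nr_ids].T @ wa
        q1, q0 = expit(eta1), expit(eta0)
        w1_row = w1[rl]
        gb = -(w1_row * q1 + (1.0 - w1_row) * q0)
        grad[1 + k : 1 + k + n_m] += np.bincount(exp.pos[nr_row], weights=gb, minlength=n_m)
        grad[1 + k + n_m : 1 + 2 * k + n_m] += data.X[exp.ridx[nr_row]].T @ gb
        grad[1 + 2 * k + n_m] += float(np.sum(-w1_row * q1))
        if gamma:
            grad[-1] += float(gb @ tcol[nr_row])

    return ll, grad


def attempts_loglik(
    params: AttemptParams,
    records: Union[AttemptData, Sequence[ParticipantRecord]],
) -> float:
    """Full log-likelihood of the attempt histories and observed outcomes.

    Four branches: phone responders contribute their success at attempt t and
    failures at 1..t-1; email responders failures at 1..t and success at the
    email attempt; nonresponders contribute all-failure products (including
    the email attempt when made) with the outcome summed out.  Empty failure
    products are one.
    """
    data = _as_data(records)
    if data.k != params.k:
        raise DataValidationError("parameter/covariate dimension mismatch")
    exp = _Expansion.build(data)
    gamma = params.gamma_email_calls != 0.0
    ll, _ = _loglik_grad(_theta_from_params(params, exp, gamma), data, exp, gamma)
    if not np.isfinite(ll):
        raise FloatingPointError("attempts log-likelihood overflowed; parameters too extreme")
    return ll


def _names(cov_names: Sequence[str], present: np.ndarray, gamma: bool) -> tuple[str, ...]:
    b0_names = tuple(
        "beta0_email" if m == EMAIL_ATTEMPT else f"beta0_{m}" for m in present
    )
    names = (
        ("alpha0",)
        + tuple(f"alpha1_{c}" for c in cov_names)
        + b0_names
        + tuple(f"beta1_{c}" for c in cov_names)
        + ("beta2",)
    )
    return names + ("gamma_email_calls",) if gamma else names


def _params_from_theta(
    theta: np.ndarray, k: int, present: np.ndarray, gamma: bool
) -> AttemptParams:
    n_m = present.size
    beta0_m = np.full(N_ATTEMPTS, np.nan)
    beta0_m[present - 1] = theta[1 + k : 1 + k + n_m]
    return AttemptParams(
        alpha0=float(theta[0]),
        alpha1=theta[1 : 1 + k],
        beta0_m=beta0_m,
        beta1=theta[1 + k + n_m : 1 + 2 * k + n_m],
        beta2=float(theta[1 + 2 * k + n_m]),
        gamma_email_calls=float(theta[-1]) if gamma else 0.0,
    )


def _check_identifiable(data: AttemptData) -> None:
    resp = data.r == 1
    if not resp.any():
        raise DegenerateDataError("no responders: outcome model unidentifiable")
    yr = data.y[resp]
    if yr.min() == yr.max():
        raise DegenerateDataError("single outcome class among responders")


def _attempt_design(
    data: AttemptData, exp: _Expansion, gamma: bool
) -> np.ndarray:
    dummies = np.zeros((exp.m.size, exp.present.size))
    dummies[np.arange(exp.m.size), exp.pos] = 1.0
    cols = [dummies, data.X[exp.ridx]]
    if gamma:
        cols.append(
            np.where(exp.m == EMAIL_ATTEMPT, data.t[exp.ridx], 0).astype(float)[:, None]
        )
    return np.column_stack(cols)


def _attempt_level_logit(exp: _Expansion, design: np.ndarray):
    """Logistic regression of attempt success on the expanded design.

    Uses the package's own quasi-Newton driver with an exact Hessian for the
    SEs: sparse attempt strata with no successes (quasi-separation) then
    surface as a flagged message and NaN SEs instead of a crash."""
    s = exp.s.astype(float)
    n_m = exp.present.size
    # condition the covariate columns; the dummy block spans the constant,
    # so centring/scaling leaves the model space unchanged
    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    mu[:n_m] = 0.0
    sd[:n_m] = 1.0
    sd = np.where(sd > 0, sd, 1.0)
    design_std = (design - mu) / sd

    def fun(theta: np.ndarray):
        eta = design_std @ theta
        ll = float(np.sum(log_expit(np.where(s == 1, eta, -eta))))
        return ll, design_std.T @ (s - expit(eta))

    res = maximize_loglik(fun, np.zeros(design.shape[1]))
    theta_raw = res.x / sd
    theta_raw[:n_m] -= float(res.x[n_m:] @ (mu[n_m:] / sd[n_m:]))
    res.x = theta_raw
    eta = design @ res.x
    ll = float(np.sum(log_expit(np.where(s == 1, eta, -eta))))
    w = expit(eta) * expit(-eta)
    info = design.T @ (design * w[:, None])
    se, _, se_msg = se_from_information(info)
    msgs = []
    if se_msg:
        msgs.append(se_msg)
    n_succ = np.bincount(exp.pos, weights=exp.s, minlength=exp.present.size)
    n_rows = np.bincount(exp.pos, minlength=exp.present.size)
    for m, ns, nr in zip(exp.present, n_succ, n_rows):
        if ns == 0 or ns == nr:
            label = "email" if m == EMAIL_ATTEMPT else str(m)
            msgs.append(f"attempt {label}: all-{'failure' if ns == 0 else 'success'} "
                        "stratum; intercept poorly identified")
    return res.x, se, ll, res.converged, "; ".join(msgs)


def fit_mar_attempts(
    records: Union[AttemptData, Sequence[ParticipantRecord]],
    email_depends_on_calls: bool = False,
) -> FitResult:
    """MAR fit (beta2 = 0) as two separate logistic regressions: the outcome
    on the complete cases, and attempt success on per-attempt indicator
    variables plus covariates over the attempt-level expansion (one row per
    attempt made)."""
    data = _as_data(records)
    _check_identifiable(data)
    exp = _Expansion.build(data)
    if exp.s.min() == exp.s.max():
        raise DegenerateDataError("attempt-success indicator constant: regression degenerate")
    resp = data.r == 1
    out_res = _logit_fit(data.y[resp], data.X[resp])

    design = _attempt_design(data, exp, email_depends_on_calls)
    att_params, att_se, _, att_conv, att_msg = _attempt_level_logit(exp, design)

    k, n_m = data.k, exp.present.size
    gamma = email_depends_on_calls
    theta = np.concatenate(
        [np.asarray(out_res.params), att_params[: n_m + k], [0.0]]
        + ([[att_params[n_m + k]]] if gamma else [])
    )
    params = _params_from_theta(theta, k, exp.present, gamma)
    se = np.concatenate(
        [np.asarray(out_res.bse), att_se[: n_m + k], [np.nan]]
        + ([[att_se[n_m + k]]] if gamma else [])
    )
    converged = bool(out_res.mle_retvals["converged"] and att_conv)
    msg = "; ".join(
        m for m in ("MAR fit via separate logistic regressions", att_msg) if m
    )
    return FitResult(
        params=params,
        names=_names(data.names, exp.present, gamma),
        estimates=theta,
        se=se,
        loglik=attempts_loglik(params, data),
        converged=converged,
        n_used=data.n,
        fixed_beta2=0.0,
        message=msg,
    )


def fit_mnar_attempts(
    records: Union[AttemptData, Sequence[ParticipantRecord]],
    start: Optional[AttemptParams] = None,
    email_depends_on_calls: bool = False,
) -> FitResult:
    """Jointly maximise the full attempt-level likelihood including beta2,
    warm-started from the MAR fit; observed-information SEs and a Wald CI
    for beta2 (via ``FitResult.wald_ci('beta2')``)."""
    data = _as_data(records)
    _check_identifiable(data)
    exp = _Expansion.build(data)
    gamma = email_depends_on_calls
    if start is None:
        start = fit_mar_attempts(data, email_depends_on_calls=gamma).params
    k, n_m = data.k, exp.present.size

    std = Standardizer.fit(data.X)
    data_std = replace(data, X=std.transform(data.X))
    a0s, a1s = std.coef_to_std(start.alpha0, start.alpha1)
    b1s = start.beta1 * std.scale
    b0s = start.beta0_m[exp.present - 1] + float(start.beta1 @ std.mean)
    theta0 = np.concatenate([[a0s], a1s, b0s, b1s, [start.beta2]])
    if gamma:
        theta0 = np.concatenate([theta0, [start.gamma_email_calls]])

    def fun(theta: np.ndarray):
        return _loglik_grad(theta, data_std, exp, gamma)

    res = maximize_loglik(fun, theta0)
    theta_std = res.x
    a0, a1 = std.coef_to_raw(theta_std[0], theta_std[1 : 1 + k])
    b1 = theta_std[1 + k + n_m : 1 + 2 * k + n_m] / std.scale
    b0 = theta_std[1 + k : 1 + k + n_m] - float(b1 @ std.mean)
    theta_raw = np.concatenate(
        [[a0], a1, b0, b1, theta_std[1 + 2 * k + n_m :]]
    )
    params = _params_from_theta(theta_raw, k, exp.present, gamma)

    def raw_grad(theta: np.ndarray) -> np.ndarray:
        _, g = _loglik_grad(theta, data, exp, gamma)
        return g

    info = observed_information(raw_grad, theta_raw)
    se, cov, se_msg = se_from_information(info)
    ll = attempts_loglik(params, data)
    msg = "; ".join(m for m in (res.message if not res.converged else "", se_msg) if m)
    return FitResult(
        params=params,
        names=_names(data.names, exp.present, gamma),
        estimates=theta_raw,
        se=se,
        loglik=ll,
        converged=res.converged,
        n_used=data.n,
        fixed_beta2=None,
        message=msg,
        cov=cov,
    )


def interaction_diagnostics(
    records: Union[AttemptData, Sequence[ParticipantRecord]]
) -> pd.DataFrame:
    """Likelihood-ratio checks of the shared-covariate-effect assumption in
    the MAR attempt-level regression: per covariate, an attempt-number x
    covariate interaction and an email-only x covariate interaction."""
    data = _as_data(records)
    _check_identifiable(data)
    exp = _Expansion.build(data)
    base_design = _attempt_design(data, exp, gamma=False)
    _, _, base_llf, _, _ = _attempt_level_logit(exp, base_design)
    m_lin = exp.m.astype(float)
    is_email = (exp.m == EMAIL_ATTEMPT).astype(float)
    has_email = bool(is_email.any())
    rows = []
    for j, cov in enumerate(data.names):
        xc = data.X[exp.ridx, j]
        if np.ptp(xc) == 0:
            for test in ("attempt_x_covariate", "email_x_covariate"):
                rows.append(
                    {"covariate": cov, "test": test, "statistic": np.nan, "df": 1,
                     "pvalue": np.nan, "note": "inestimable (constant covariate)"}
                )
            continue
        for test, extra in (
            ("attempt_x_covariate", m_lin * xc),
            ("email_x_covariate", is_email * xc),
        ):
            if test == "email_x_covariate" and not has_email:
                rows.append(
                    {"covariate": cov, "test": test, "statistic": np.nan, "df": 1,
                     "pvalue": np.nan, "note": "inestimable (no email attempts)"}
                )
                continue
            design = np.column_stack([base_design, extra])
            try:
                _, _, llf, _, _ = _attempt_level_logit(exp, design)
                stat = max(0.0, 2.0 * (llf - base_llf))
                rows.append(
                    {"covariate": cov, "test": test, "statistic": stat, "df": 1,
                     "pvalue": float(chi2.sf(stat, 1)), "note": ""}
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                rows.append(
                    {"covariate": cov, "test": test, "statistic": np.nan, "df": 1,
                     "pvalue": np.nan, "note": f"inestimable ({exc})"}
                )
    return pd.DataFrame(rows)


def attempt_trend_regression(table: AttemptSummaryTable) -> tuple[float, float]:
    """Grouped complete-case logistic regression of the quit proportion on
    the phone-call count, over the phone-responder rows (email rows are
    excluded); returns (slope, standard error)."""
    rows = table.phone_responder_rows()
    rows = rows[rows["responders"] > 0]
    if rows["phone_calls"].nunique() < 2:
        raise DegenerateDataError("need at least two distinct attempt counts")
    endog = np.column_stack(
        [rows["quitters"], rows["responders"] - rows["quitters"]]
    ).astype(float)
    exog = sm.add_constant(rows["phone_calls"].astype(float))
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    return float(res.params.iloc[1]), float(res.bse.iloc[1])


def _apply_spec(data: AttemptData, spec: RobustnessSpec) -> AttemptData:
    d = data
    if spec.participants != "all":
        age = d.X[:, d.names.index("age")] if "age" in d.names else None
        sex = d.X[:, d.names.index("sex")] if "sex" in d.names else None
        if spec.participants in ("age_le_median", "age_gt_median"):
            if age is None:
                raise DegenerateDataError("age not available for age split")
            med = float(np.median(age))
            mask = age <= med if spec.participants == "age_le_median" else age > med
        elif spec.participants in ("men", "women"):
            if sex is None:
                raise DegenerateDataError("sex not available for sex split")
            mask = sex == (0 if spec.participants == "men" else 1)
        elif spec.participants == "max5calls":
            mask = d.t <= 5
        else:
            raise ValueError(f"unknown participant filter {spec.participants!r}")
        d = d.subset_rows(mask)
    if spec.covariates == "all":
        keep = list(d.names)
    elif spec.covariates == "smoking":
        keep = [c for c in d.names if c in SMOKING_RELATED]
    elif spec.covariates == "non_smoking":
        keep = [c for c in d.names if c not in SMOKING_RELATED]
    elif spec.covariates == "none":
        keep = []
    elif spec.covariates == "all_except_sex":
        keep = [c for c in d.names if c != "sex"]
    else:
        raise ValueError(f"unknown covariate subset {spec.covariates!r}")
    return d.select_covariates(keep)


def robustness_suite(
    records: Union[AttemptData, Sequence[ParticipantRecord]],
    specs: Optional[Sequence[RobustnessSpec]] = None,
) -> pd.DataFrame:
    """Refit the MNAR attempts model under each robustness spec and collect
    beta2 estimates and SEs; per-row failures are recorded and the suite
    continues."""
    data = _as_data(records)
    if specs is None:
        specs = default_robustness_specs()
    rows = []
    for spec in specs:
        row = {
            "label": spec.label,
            "covariates": spec.covariates,
            "participants": spec.participants,
            "email_depends_on_calls": spec.email_depends_on_calls,
            "n": np.nan, "beta2": np.nan, "se": np.nan,
            "converged": False, "note": "",
        }
        try:
            sub = _apply_spec(data, spec)
            fit = fit_mnar_attempts(sub, email_depends_on_calls=spec.email_depends_on_calls)
            row.update(
                n=sub.n, beta2=fit.estimate("beta2"), se=fit.se_of("beta2"),
                converged=fit.converged, note=fit.message,
            )
        except (DegenerateDataError, DataValidationError, FloatingPointError) as exc:
            row["note"] = f"failed: {exc}"
            logger.warning("robustness spec %r failed: %s", spec.label, exc)
        rows.append(row)
    return pd.DataFrame(rows)
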