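"""Selection-model analysis of a possibly-MNAR binary outcome.

Two logistic regressions are modelled jointly:

* outcome model:      logit P(Y=1 | x)        = alpha0 + alpha1' x
* missingness model:  logit P(R=1 | Y=y, x)   = beta0 + beta1' x + beta2 * y

For nonresponders the unobserved outcome is marginalised (summed) out of the
likelihood, so every participant contributes.  ``beta2`` is the adjusted
log odds ratio between outcome and response: 0 means MAR, large positive
values approach the "missing = not abstained" convention.  ``beta2`` equals
minus the log of the informatively-missing odds ratio (IMOR), which gives a
simple conversion between ``beta2`` and the implied abstention probability
among nonresponders for a typical participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, log_expit, logit
from scipy.stats import chi2

from ._optim import (
    FitResult,
    Standardizer,
    Z_95,
    maximize_loglik,
    observed_information,
    se_from_information,
)
from .core_data import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATES,
    ParticipantRecord,
)
from .exceptions import DataValidationError, DegenerateDataError

logger = logging.getLogger(__name__)

#: Fixed large |beta2| used as a proxy for the "missing = not abstained"
#: limit (beta2 -> +inf) without numerical overflow.
LARGE_BETA2 = 15.0

#: Default sensitivity grid for the fixed-beta2 analysis.
DEFAULT_BETA2_GRID = (-4.0, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass
class SelectionParams:
    """Parameters of the joint outcome/missingness selection model."""

    alpha0: float
    alpha1: np.ndarray
    beta0: float
    beta1: np.ndarray
    beta2: float = 0.0

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.alpha1.shape != self.beta1.shape or self.alpha1.ndim != 1:
            raise DataValidationError("alpha1 and beta1 must be 1-d vectors of equal length")
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise DataValidationError("selection parameters must be finite")

    @property
    def k(self) -> int:
        return self.alpha1.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.alpha0], self.alpha1, [self.beta0], self.beta1, [self.beta2]]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, k: int) -> "SelectionParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size != 2 * k + 3:
            raise DataValidationError(f"expected {2*k+3} parameters, got {theta.size}")
        return cls(
            alpha0=float(theta[0]),
            alpha1=theta[1 : 1 + k],
            beta0=float(theta[1 + k]),
            beta1=theta[2 + k : 2 + 2 * k],
            beta2=float(theta[2 + 2 * k]),
        )


@dataclass(frozen=True)
class SelectionData:
    """Array view of a cohort used by the likelihood routines; covariate
    subsets used in robustness analyses slice ``X`` and ``names``."""

    X: np.ndarray
    y: np.ndarray  # -1 where missing
    r: np.ndarray
    names: tuple[str, ...] = COVARIATES

    @classmethod
    def from_records(cls, records: Sequence[ParticipantRecord]) -> "SelectionData":
        if len(records) == 0:
            raise DataValidationError("empty cohort")
        X = np.stack([rec.x for rec in records])
        y = np.array([-1 if rec.y is None else rec.y for rec in records], dtype=int)
        r = np.array([rec.r for rec in records], dtype=int)
        return cls(X=X, y=y, r=r)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _as_data(records: Union[SelectionData, Sequence[ParticipantRecord]]) -> SelectionData:
    return records if isinstance(records, SelectionData) else SelectionData.from_records(records)


def outcome_probability(params: SelectionParams, x: np.ndarray) -> np.ndarray:
    """P(Y=1 | x) under the outcome model; stable for extreme predictors."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.k:
        raise DataValidationError(f"x has {x.shape[-1]} covariates, expected {params.k}")
    return expit(params.alpha0 + x @ params.alpha1)


def response_probability(params: SelectionParams, x: np.ndarray, y) -> np.ndarray:
    """P(R=1 | Y=y, x) under the missingness model."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.k:
        raise DataValidationError(f"x has {x.shape[-1]} covariates, expected {params.k}")
    return expit(params.beta0 + x @ params.beta1 + params.beta2 * np.asarray(y))


def _loglik_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, r: np.ndarray):
    """Marginal log-likelihood and analytic gradient at a flat parameter
    vector [alpha0, alpha1, beta0, beta1, beta2]."""
    n, k = X.shape
    a0, a1 = theta[0], theta[1 : 1 + k]
    b0, b1, b2 = theta[1 + k], theta[2 + k : 2 + 2 * k], theta[2 + 2 * k]
    a_lin = a0 + X @ a1
    b_lin = b0 + X @ b1
    resp = r == 1
    nonr = ~resp
    grad = np.zeros_like(theta)
    ll = 0.0

    if resp.any():
        yr = y[resp].astype(float)
        al = a_lin[resp]
        eta = b_lin[resp] + b2 * yr
        ll += float(np.sum(log_expit(np.where(yr == 1, al, -al))))
        ll += float(np.sum(log_expit(eta)))  # success terms, R=1
        wa = yr - expit(al)
        wb = 1.0 - expit(eta)
        Xr = X[resp]
        grad[0] += wa.sum()
        grad[1 : 1 + k] += Xr.T @ wa
        grad[1 + k] += wb.sum()
        grad[2 + k : 2 + 2 * k] += Xr.T @ wb
        grad[2 + 2 * k] += float(wb @ yr)

    if nonr.any():
        al = a_lin[nonr]
        eta0 = b_lin[nonr]
        eta1 = eta0 + b2
        l1 = log_expit(al) + log_expit(-eta1)  # y=1 branch, attempt fails
        l0 = log_expit(-al) + log_expit(-eta0)
        lse = np.logaddexp(l1, l0)
        ll += float(lse.sum())
        w1 = np.exp(l1 - lse)
        wa = w1 - expit(al)
        q1, q0 = expit(eta1), expit(eta0)
        gb = -(w1 * q1 + (1.0 - w1) * q0)
        Xn = X[nonr]
        grad[0] += wa.sum()
        grad[1 : 1 + k] += Xn.T @ wa
        grad[1 + k] += gb.sum()
        grad[2 + k : 2 + 2 * k] += Xn.T @ gb
        grad[2 + 2 * k] += float(np.sum(-w1 * q1))

    return ll, grad


def selection_loglik(
    params: SelectionParams,
    records: Union[SelectionData, Sequence[ParticipantRecord]],
) -> float:
    """Eq.-(3)-style marginal log-likelihood: responders contribute
    log[P(Y=y|x) P(R=1|y,x)], nonresponders log[sum_y P(Y=y|x) P(R=0|y,x)]."""
    data = _as_data(records)
    if data.k != params.k:
        raise DataValidationError("parameter/covariate dimension mismatch")
    ll, _ = _loglik_grad(params.to_vector(), data.X, data.y, data.r)
    if not np.isfinite(ll):
        raise FloatingPointError("selection log-likelihood overflowed; parameters too extreme")
    return ll


def _param_names(cov_names: Sequence[str]) -> tuple[str, ...]:
    return (
        ("alpha0",)
        + tuple(f"alpha1_{c}" for c in cov_names)
        + ("beta0",)
        + tuple(f"beta1_{c}" for c in cov_names)
        + ("beta2",)
    )


def _check_identifiable(data: SelectionData) -> None:
    resp = data.r == 1
    if not resp.any():
        raise DegenerateDataError("no responders: outcome model unidentifiable")
    yr = data.y[resp]
    if yr.min() == yr.max():
        raise DegenerateDataError("single outcome class among responders")


def _logit_fit(endog: np.ndarray, X: np.ndarray):
    """Conventional logistic regression; separation surfaces as an error."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    model = sm.Logit(endog, sm.add_constant(X, has_constant="add"))
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise DegenerateDataError(f"logistic regression failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise DegenerateDataError("logistic regression diverged (separation?)")
    return res


def fit_mar(records: Union[SelectionData, Sequence[ParticipantRecord]]) -> FitResult:
    """MAR fit (beta2 = 0) as two separate conventional logistic regressions:
    the outcome model on the complete cases and the missingness model on all
    participants.  Their stacked estimates maximise the marginal likelihood
    at beta2 = 0, and the combined log-likelihood equals
    :func:`selection_loglik` there."""
    data = _as_data(records)
    _check_identifiable(data)
    if data.r.min() == data.r.max():
        raise DegenerateDataError(
            "response indicator is constant: missingness regression degenerate"
        )
    resp = data.r == 1
    out_res = _logit_fit(data.y[resp], data.X[resp])
    mis_res = _logit_fit(data.r, data.X)
    k = data.k
    params = SelectionParams(
        alpha0=float(out_res.params[0]),
        alpha1=np.asarray(out_res.params[1:]),
        beta0=float(mis_res.params[0]),
        beta1=np.asarray(mis_res.params[1:]),
        beta2=0.0,
    )
    se = np.concatenate([out_res.bse, mis_res.bse, [np.nan]])
    converged = bool(out_res.mle_retvals["converged"] and mis_res.mle_retvals["converged"])
    if not converged:
        logger.warning("MAR component regression did not converge")
    return FitResult(
        params=params,
        names=_param_names(data.names),
        estimates=params.to_vector(),
        se=se,
        loglik=selection_loglik(params, data),
        converged=converged,
        n_used=data.n,
        fixed_beta2=0.0,
        message="MAR fit via separate logistic regressions",
    )


def _fit_ml(
    data: SelectionData,
    start: SelectionParams,
    fixed_beta2: Optional[float],
) -> FitResult:
    """Maximise the marginal likelihood by quasi-Newton iteration on an
    internally standardised covariate scale, with observed-information SEs
    computed on the raw scale."""
    k = data.k
    std = Standardizer.fit(data.X)
    Xs = std.transform(data.X)

    a0s, a1s = std.coef_to_std(start.alpha0, start.alpha1)
    b0s, b1s = std.coef_to_std(start.beta0, start.beta1)
    b2_start = fixed_beta2 if fixed_beta2 is not None else start.beta2

    def pack(theta_free: np.ndarray) -> np.ndarray:
        if fixed_beta2 is None:
            return theta_free
        return np.concatenate([theta_free, [fixed_beta2]])

    def fun(theta_free: np.ndarray):
        ll, g = _loglik_grad(pack(theta_free), Xs, data.y, data.r)
        return (ll, g if fixed_beta2 is None else g[:-1])

    theta0 = np.concatenate([[a0s], a1s, [b0s], b1s, [b2_start]])
    if fixed_beta2 is not None:
        theta0 = theta0[:-1]
    res = maximize_loglik(fun, theta0)
    theta_std = pack(res.x)

    a0, a1 = std.coef_to_raw(theta_std[0], theta_std[1 : 1 + k])
    b0, b1 = std.coef_to_raw(theta_std[1 + k], theta_std[2 + k : 2 + 2 * k])
    params = SelectionParams(alpha0=a0, alpha1=a1, beta0=b0, beta1=b1, beta2=float(theta_std[-1]))
    theta_raw = params.to_vector()

    free_idx = np.arange(theta_raw.size if fixed_beta2 is None else theta_raw.size - 1)

    def raw_grad(theta_free: np.ndarray) -> np.ndarray:
        full = theta_raw.copy()
        full[free_idx] = theta_free
        _, g = _loglik_grad(full, data.X, data.y, data.r)
        return g[free_idx]

    info = observed_information(raw_grad, theta_raw[free_idx])
    se_free, cov, se_msg = se_from_information(info)
    se = np.full(theta_raw.size, np.nan)
    se[free_idx] = se_free
    ll = selection_loglik(params, data)
    msg = "; ".join(m for m in (res.message if not res.converged else "", se_msg) if m)
    return FitResult(
        params=params,
        names=_param_names(data.names),
        estimates=theta_raw,
        se=se,
        loglik=ll,
        converged=res.converged,
        n_used=data.n,
        fixed_beta2=fixed_beta2,
        message=msg,
        cov=cov,
    )


def fit_fixed_beta2(
    records: Union[SelectionData, Sequence[ParticipantRecord]],
    beta2: float,
    start: Optional[SelectionParams] = None,
) -> FitResult:
    """Maximise the marginal likelihood with the sensitivity parameter
    ``beta2`` held fixed; all other parameters are free."""
    data = _as_data(records)
    _check_identifiable(data)
    if start is None:
        start = fit_mar(data).params
    return _fit_ml(data, start, fixed_beta2=float(beta2))


def fit_full_mnar(
    records: Union[SelectionData, Sequence[ParticipantRecord]],
    start: Optional[SelectionParams] = None,
    multistart_beta2: Sequence[float] = (-2.0, 0.0, 2.0),
) -> FitResult:
    """Jointly maximise the marginal likelihood over all parameters
    including ``beta2``.  The SE of ``beta2`` is typically very large: the
    parameter is only weakly identified by the linearity assumptions of the
    missingness model.

    Because the likelihood can be flat or multimodal in ``beta2``, the
    default run warm-starts from fixed-beta2 fits at several values and
    keeps the best joint optimum; pass ``start`` to use a single start.
    """
    data = _as_data(records)
    _check_identifiable(data)
    if start is not None:
        return _fit_ml(data, start, fixed_beta2=None)
    mar = fit_mar(data).params
    best: Optional[FitResult] = None
    for b2 in multistart_beta2:
        warm = mar if b2 == 0.0 else fit_fixed_beta2(data, b2, start=mar).params
        fit = _fit_ml(data, warm, fixed_beta2=None)
        if best is None or (fit.converged and fit.loglik > best.loglik):
            best = fit
    assert best is not None
    return best


def beta2_to_missing_abstention(beta2: float, p_cc: float) -> float:
    """Implied abstention probability among nonresponders, for a typical
    participant whose complete-case abstention probability is ``p_cc``:
    ``inverse-logit(logit(p_cc) - beta2)``, using that beta2 = -log(IMOR)."""
    if not 0.0 < p_cc < 1.0:
        raise ValueError("p_cc must lie strictly between 0 and 1")
    return float(expit(logit(p_cc) - beta2))


def complete_case_abstention(
    records: Union[SelectionData, Sequence[ParticipantRecord]]
) -> float:
    """Observed abstention rate among responders, P(Y=1 | R=1)."""
    data = _as_data(records)
    resp = data.r == 1
    if not resp.any():
        raise DegenerateDataError("no responders")
    return float(np.mean(data.y[resp]))


@dataclass
class SensitivityRow:
    beta2: float
    p_a: float
    fit: FitResult


@dataclass
class SensitivityTable:
    """One fixed-beta2 fit per grid value, with the implied nonresponder
    abstention probability ``p_a`` for a typical participant."""

    rows: list[SensitivityRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = []
        for row in self.rows:
            f = row.fit
            for name, est, se in zip(f.names, f.estimates, f.se):
                z = est / se if se and np.isfinite(se) and se > 0 else np.nan
                out.append(
                    {
                        "beta2": row.beta2,
                        "p_a": row.p_a,
                        "parameter": name,
                        "estimate": est,
                        "se": se,
                        "significant": bool(np.isfinite(z) and abs(z) > Z_95),
                        "loglik": f.loglik,
                        "converged": f.converged,
                    }
                )
        return pd.DataFrame(out)

    def layout_frame(self, parameters: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Wide layout: one column per beta2 value with 'estimate (se)' cells,
        bold-marked (*) when |estimate/se| > 1.96."""
        cols = {}
        for row in self.rows:
            f = row.fit
            cells = {}
            names = parameters or [n for n in f.names if n.startswith("beta1_")]
            for name in names:
                est, se = f.estimate(name), f.se_of(name)
                star = "*" if np.isfinite(se) and se > 0 and abs(est / se) > Z_95 else ""
                cells[name] = f"{est:.3f} ({se:.3f}){star}"
            cols[f"beta2={row.beta2:g} (Pa={row.p_a:.2f})"] = cells
        return pd.DataFrame(cols)


def sensitivity_grid(
    records: Union[SelectionData, Sequence[ParticipantRecord]],
    beta2_values: Sequence[float] = DEFAULT_BETA2_GRID,
    anchor: float = 0.0,
) -> SensitivityTable:
    """Fixed-beta2 sensitivity analysis over a grid.

    The anchor value (default 0, the MAR fit) is fitted first; fits then
    expand outward, each warm-started from its inner neighbour's estimates.
    Per-row convergence failures are recorded and the grid continues.
    """
    data = _as_data(records)
    values = sorted(float(v) for v in beta2_values)
    if anchor not in values:
        raise ValueError("beta2 grid must contain the anchor value")
    p_cc = complete_case_abstention(data)

    fits: dict[float, FitResult] = {}
    anchor_fit = fit_mar(data) if anchor == 0.0 else fit_fixed_beta2(data, anchor)
    fits[anchor] = anchor_fit

    def expand(seq: list[float]) -> None:
        prev = anchor_fit
        for v in seq:
            try:
                fit = fit_fixed_beta2(data, v, start=prev.params)
            except DegenerateDataError as exc:  # pragma: no cover - defensive
                logger.warning("sensitivity fit at beta2=%s failed: %s", v, exc)
                continue
            fits[v] = fit
            if fit.converged:
                prev = fit
            else:
                logger.warning("sensitivity fit at beta2=%s did not converge", v)

    expand([v for v in values if v > anchor])
    expand([v for v in reversed(values) if v < anchor])

    table = SensitivityTable()
    for v in values:
        if v in fits:
            table.rows.append(
                SensitivityRow(beta2=v, p_a=beta2_to_missing_abstention(v, p_cc), fit=fits[v])
            )
    return table


# ---------------------------------------------------------------------------
# Covariate-coding diagnostics


def _collapse_sparse(levels: np.ndarray, counts_of, min_count: int) -> np.ndarray:
    """Merge levels observed fewer than ``min_count`` times into their nearest
    neighbouring level (toward the centre of the scale)."""
    vals = np.array(sorted(set(levels)))
    merged = levels.astype(float).copy()
    changed = True
    while changed and len(vals) > 2:
        changed = False
        for v in vals:
            if np.sum(merged == v) < min_count:
                others = vals[vals != v]
                target = others[np.argmin(np.abs(others - v))]
                logger.warning(
                    "collapsing sparse category %g into %g (<%d observations)",
                    v, target, min_count,
                )
                merged[merged == v] = target
                vals = np.array(sorted(set(merged)))
                changed = True
                break
    return merged


def _lr_pvalue(ll_big: float, ll_small: float, df: int) -> tuple[float, float]:
    stat = max(0.0, 2.0 * (ll_big - ll_small))
    return stat, float(chi2.sf(stat, df)) if df > 0 else np.nan


def coding_adequacy_tests(
    records: Union[SelectionData, Sequence[ParticipantRecord]],
    min_cell: int = 5,
) -> pd.DataFrame:
    """Deviance checks of the continuous coding of ordinal covariates and of
    quadratic terms for the continuous covariates.

    For each ordinal-score covariate, compares the logistic regression that
    treats it as continuous against one using category indicator variables
    (likelihood-ratio test), for both the complete-case outcome regression
    and the all-participant missingness regression.  Adds quadratic-term
    tests for age and conscientiousness.  Sparse categories are collapsed
    into a neighbour with a logged warning; binary covariates are skipped.
    """
    data = _as_data(records)
    _check_identifiable(data)
    resp = data.r == 1
    targets = {
        "outcome": (data.y[resp].astype(float), data.X[resp]),
        "missingness": (data.r.astype(float), data.X),
    }
    rows = []
    for model_name, (endog, X) in targets.items():
        if endog.min() == endog.max():
            raise DegenerateDataError(f"{model_name} regression degenerate: constant response")
        base = _logit_fit(endog, X)
        for cov in CATEGORICAL_COVARIATES:
            if cov not in data.names:
                continue
            j = data.names.index(cov)
            col = _collapse_sparse(X[:, j], None, min_cell)
            levels = np.unique(col)
            if levels.size <= 2:
                rows.append(
                    {"covariate": cov, "model": model_name,
                     "test": "categorical_vs_continuous", "statistic": np.nan,
                     "df": 0, "pvalue": np.nan,
                     "note": "skipped (<=2 levels: categorical == continuous)"}
                )
                continue
            # replace the linear column by L-1 dummies (reference = lowest)
            dummies = np.column_stack([(col == lv).astype(float) for lv in levels[1:]])
            X_cat = np.column_stack([np.delete(X, j, axis=1), dummies])
            cat = _logit_fit(endog, X_cat)
            stat, p = _lr_pvalue(cat.llf, base.llf, df=levels.size - 2)
            rows.append(
                {"covariate": cov, "model": model_name,
                 "test": "categorical_vs_continuous", "statistic": stat,
                 "df": levels.size - 2, "pvalue": p, "note": ""}
            )
        for cov in CONTINUOUS_COVARIATES:
            if cov not in data.names:
                continue
            j = data.names.index(cov)
            col = X[:, j]
            quad = ((col - col.mean()) / max(col.std(), 1e-12)) ** 2
            X_quad = np.column_stack([X, quad])
            qfit = _logit_fit(endog, X_quad)
            stat, p = _lr_pvalue(qfit.llf, base.llf, df=1)
            rows.append(
                {"covariate": cov, "model": model_name, "test": "quadratic_term",
                 "statistic": stat, "df": 1, "pvalue": p, "note": ""}
            )
    return pd.DataFrame(rows)
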