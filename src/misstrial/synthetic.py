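"""Synthetic trial cohorts with known ground truth.

Generates participant-level data from the same generative models the fitting
code assumes: covariates from independent marginal distributions, the binary
outcome from the logistic outcome model, and the contact process from the
attempt-level missingness model (per-attempt intercepts, shared covariate
effects, an outcome effect ``beta2``) with an outcome-independent random
budget of available phone calls and an email-availability probability.

The true outcome of every participant — including nonresponders — is kept in
a shadow table for validation; it is never passed to fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .attempts import AttemptParams
from .core_data import (
    COVARIATES,
    EMAIL_ATTEMPT,
    MAX_PHONE_CALLS,
    AttemptRecord,
    AttemptSummaryTable,
    ParticipantRecord,
)
from .exceptions import DataValidationError


@dataclass(frozen=True)
class BinaryCovariate:
    """Bernoulli marginal."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DataValidationError(f"probability {self.p} outside [0,1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)


@dataclass(frozen=True)
class BoundedScore:
    """Gaussian draw rounded to a step grid and clipped to [low, high];
    used for age (integer years) and the ordinal questionnaire scores."""

    mean: float
    sd: float
    low: float
    high: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.high <= self.low or self.step <= 0:
            raise DataValidationError("invalid bounded-score specification")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.normal(self.mean, self.sd, size=n)
        z = np.round((z - self.low) / self.step) * self.step + self.low
        return np.clip(z, self.low, self.high)


CovariateSpec = Union[BinaryCovariate, BoundedScore]


@dataclass
class CohortConfig:
    """Ground-truth configuration of a synthetic cohort."""

    n: int
    covariates: dict[str, CovariateSpec]
    alpha0: float
    alpha1: np.ndarray
    attempt_params: AttemptParams
    call_budget_pmf: np.ndarray
    email_availability: float

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.call_budget_pmf = np.asarray(self.call_budget_pmf, dtype=float)
        if self.n < 1:
            raise DataValidationError("cohort size must be >= 1")
        if tuple(self.covariates) != tuple(COVARIATES[: len(self.covariates)]):
            # order matters: coefficient vectors are indexed positionally
            if set(self.covariates) == set(COVARIATES):
                self.covariates = {c: self.covariates[c] for c in COVARIATES}
            else:
                raise DataValidationError("covariate spec must cover the fixed covariate set")
        if self.alpha1.shape != (len(self.covariates),):
            raise DataValidationError("alpha1 length must match the covariate count")
        if self.call_budget_pmf.shape != (MAX_PHONE_CALLS,):
            raise DataValidationError(f"call budget pmf must have length {MAX_PHONE_CALLS}")
        if abs(self.call_budget_pmf.sum() - 1.0) > 1e-9 or (self.call_budget_pmf < 0).any():
            raise DataValidationError("call budget pmf must be a probability vector")
        if not 0.0 <= self.email_availability <= 1.0:
            raise DataValidationError("email availability outside [0,1]")


# Calibrated so that, under the default attempt process, the model-implied
# abstention rate among responders is ~0.22 and the missingness rate ~0.59.
_DEFAULT_ALPHA0 = -3.131
_DEFAULT_ALPHA1 = (-0.05, 0.020, 0.10, 0.08, -0.08, 0.10, 0.25, 0.05, -0.12, -0.35)
_DEFAULT_BETA1 = (-0.099, 0.021, 0.103, 0.034, -0.026, -0.009, -0.002, 0.096, 0.020, -0.072)
_DEFAULT_BETA0_M = (
    -2.643, -2.721, -2.798, -2.876, -2.954, -3.032, -3.110, -3.187, -3.265, -3.343,
    -3.443,
)
_DEFAULT_BETA2 = 0.2
#: Budget of available phone calls: most mass at a single call plus the
#: email 'last ditch' attempt, a secondary mass at the full ten calls.
_DEFAULT_BUDGET_PMF = (0.65, 0.08, 0.055, 0.035, 0.03, 0.012, 0.023, 0.012, 0.008, 0.095)
_DEFAULT_EMAIL_AVAILABILITY = 0.95


def default_iquit_config(n: int = 1758, beta2: float = _DEFAULT_BETA2) -> CohortConfig:
    """Default configuration emulating the motivating Internet-based
    cessation trial: n = 1758, covariate marginals matching the published
    baseline summary statistics, and outcome/attempt coefficients calibrated
    to ~22% abstention among responders and ~59% missingness."""
    covariates: dict[str, CovariateSpec] = {
        "treatment": BinaryCovariate(877 / 1758),
        "age": BoundedScore(38, 11, 18, 80, step=1),
        "sex": BinaryCovariate(1126 / 1758),
        "qualifications": BoundedScore(3.06, 1.16, 1, 5, step=1),
        "deprivation": BoundedScore(1.21, 1.09, 0, 5, step=1),
        "conscientiousness": BoundedScore(3.31, 0.84, 1, 5, step=0.25),
        "determination": BoundedScore(4.30, 0.75, 1, 5, step=1),
        "support": BoundedScore(3.31, 1.23, 1, 5, step=1),
        "dependence": BoundedScore(5.48, 1.57, 1, 8, step=1),
        "previous": BinaryCovariate(907 / 1758),
    }
    attempt_params = AttemptParams(
        alpha0=_DEFAULT_ALPHA0,
        alpha1=np.array(_DEFAULT_ALPHA1),
        beta0_m=np.array(_DEFAULT_BETA0_M),
        beta1=np.array(_DEFAULT_BETA1),
        beta2=beta2,
    )
    return CohortConfig(
        n=n,
        covariates=covariates,
        alpha0=_DEFAULT_ALPHA0,
        alpha1=np.array(_DEFAULT_ALPHA1),
        attempt_params=attempt_params,
        call_budget_pmf=np.array(_DEFAULT_BUDGET_PMF),
        email_availability=_DEFAULT_EMAIL_AVAILABILITY,
    )


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Draw a cohort from the configured generative process.

    For each participant: draw covariates, the true outcome, a budget of
    available phone calls and email availability; make phone attempts until
    the first success or the budget is exhausted; if all calls fail and an
    email is available, make the email attempt (index 11).  The outcome is
    recorded only when some attempt succeeded.

    Returns ``(records, shadow)`` where ``shadow`` holds every participant's
    true outcome (id, y_true, responded) for validation only.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    X = np.column_stack([spec.draw(n, rng) for spec in config.covariates.values()])
    p_y = expit(config.alpha0 + X @ config.alpha1)
    y_true = (rng.random(n) < p_y).astype(int)

    ap = config.attempt_params
    xb = X @ ap.beta1
    eta_phone = ap.beta0_m[:MAX_PHONE_CALLS][None, :] + xb[:, None] + ap.beta2 * y_true[:, None]
    phone_success = rng.random((n, MAX_PHONE_CALLS)) < expit(eta_phone)
    budget = rng.choice(np.arange(1, MAX_PHONE_CALLS + 1), size=n, p=config.call_budget_pmf)
    email_avail = rng.random(n) < config.email_availability

    within = np.arange(1, MAX_PHONE_CALLS + 1)[None, :] <= budget[:, None]
    hit = phone_success & within
    any_phone = hit.any(axis=1)
    first = hit.argmax(axis=1) + 1  # valid only where any_phone
    t = np.where(any_phone, first, budget)
    email_attempted = (~any_phone) & email_avail
    eta_email = (
        ap.beta0_m[EMAIL_ATTEMPT - 1] + xb + ap.beta2 * y_true
        + ap.gamma_email_calls * t
    )
    email_success = email_attempted & (rng.random(n) < expit(eta_email))

    records: list[ParticipantRecord] = []
    for i in range(n):
        if any_phone[i]:
            succ: Optional[int] = int(t[i])
        elif email_success[i]:
            succ = EMAIL_ATTEMPT
        else:
            succ = None
        responded = succ is not None
        records.append(
            ParticipantRecord(
                id=f"P{i + 1:05d}",
                x=X[i],
                y=int(y_true[i]) if responded else None,
                r=int(responded),
                attempts=AttemptRecord(
                    t=int(t[i]),
                    email_attempted=bool(email_attempted[i]),
                    success_attempt=succ,
                ),
            )
        )
    shadow = pd.DataFrame(
        {
            "id": [rec.id for rec in records],
            "y_true": y_true,
            "responded": [rec.r for rec in records],
        }
    )
    return records, shadow


def tabulate_attempts(records) -> AttemptSummaryTable:
    """Counts of participants, responders and quitters by
    (phone-call count, email-attempted) cell."""
    rows: dict[tuple[int, int], list[int]] = {}
    for rec in records:
        key = (rec.attempts.t, int(rec.attempts.email_attempted))
        cell = rows.setdefault(key, [0, 0, 0])
        cell[0] += 1
        cell[1] += rec.r
        cell[2] += 1 if rec.y == 1 else 0
    df = pd.DataFrame(
        [
            {"phone_calls": t, "email": e, "participants": c[0],
             "responders": c[1], "quitters": c[2]}
            for (t, e), c in sorted(rows.items())
        ]
    )
    return AttemptSummaryTable(table=df)


# ---------------------------------------------------------------------------
# Config (de)serialisation for the CLI


def config_to_yaml(config: CohortConfig, path) -> None:
    spec_d = {}
    for name, spec in config.covariates.items():
        if isinstance(spec, BinaryCovariate):
            spec_d[name] = {"kind": "binary", "p": spec.p}
        else:
            spec_d[name] = {
                "kind": "score", "mean": spec.mean, "sd": spec.sd,
                "low": spec.low, "high": spec.high, "step": spec.step,
            }
    doc = {
        "n": config.n,
        "covariates": spec_d,
        "alpha0": float(config.alpha0),
        "alpha1": [float(v) for v in config.alpha1],
        "attempts": {
            "beta0_m": [float(v) for v in config.attempt_params.beta0_m],
            "beta1": [float(v) for v in config.attempt_params.beta1],
            "beta2": float(config.attempt_params.beta2),
            "gamma_email_calls": float(config.attempt_params.gamma_email_calls),
        },
        "call_budget_pmf": [float(v) for v in config.call_budget_pmf],
        "email_availability": float(config.email_availability),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    covariates: dict[str, CovariateSpec] = {}
    for name, d in doc["covariates"].items():
        if d["kind"] == "binary":
            covariates[name] = BinaryCovariate(d["p"])
        elif d["kind"] == "score":
            covariates[name] = BoundedScore(
                d["mean"], d["sd"], d["low"], d["high"], d.get("step", 1.0)
            )
        else:
            raise DataValidationError(f"unknown covariate kind {d['kind']!r}")
    att = doc["attempts"]
    attempt_params = AttemptParams(
        alpha0=doc["alpha0"],
        alpha1=np.array(doc["alpha1"], dtype=float),
        beta0_m=np.array(att["beta0_m"], dtype=float),
        beta1=np.array(att["beta1"], dtype=float),
        beta2=float(att["beta2"]),
        gamma_email_calls=float(att.get("gamma_email_calls", 0.0)),
    )
    return CohortConfig(
        n=int(doc["n"]),
        covariates=covariates,
        alpha0=float(doc["alpha0"]),
        alpha1=np.array(doc["alpha1"], dtype=float),
        attempt_params=attempt_params,
        call_budget_pmf=np.array(doc["call_budget_pmf"], dtype=float),
        email_availability=float(doc["email_availability"]),
    )
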