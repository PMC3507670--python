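"""Bayes posterior prediction of the unobserved outcome for nonresponders.

Given a fitted attempt-level model, the posterior odds that a nonresponder
abstained combine the covariate-conditional prior odds with the likelihood
ratio of their entire failed attempt history under Y=1 versus Y=0.  The
marginal over nonresponders summarises what the model 'imputes' and a band
is obtained by shifting beta2 by +/- k standard errors with all other
parameters held at their estimates.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from ._optim import FitResult
from .attempts import AttemptData, AttemptParams, _as_data
from .core_data import EMAIL_ATTEMPT, AttemptRecord, ParticipantRecord
from .exceptions import DataValidationError, DegenerateDataError


def posterior_abstention(
    params: AttemptParams, attempts: AttemptRecord, x: np.ndarray
) -> float:
    """P(Y=1 | every attempt failed, x) for one nonresponder.

    The log posterior odds are the prior log odds alpha0 + alpha1'x plus
    sum over the attempts actually made (phone calls 1..t, the email attempt
    when made) of log[(1 - q_m(1)) / (1 - q_m(0))], where q_m(y) is the
    attempt-m success probability given Y=y.
    """
    if attempts.success_attempt is not None:
        raise DataValidationError("posterior is defined only for failed attempt histories")
    x = np.asarray(x, dtype=float)
    log_odds = params.alpha0 + float(x @ params.alpha1)
    xb = float(x @ params.beta1)
    for m in attempts.attempts_made:
        eta0 = params.beta0_m[m - 1] + xb
        if m == EMAIL_ATTEMPT:
            eta0 += params.gamma_email_calls * attempts.t
        if not np.isfinite(eta0):
            raise DataValidationError(f"beta0_m undefined for attempt {m}")
        log_odds += float(log_expit(-(eta0 + params.beta2)) - log_expit(-eta0))
    return float(expit(log_odds))


def _nonresponder_posteriors(
    params: AttemptParams,
    records: Union[AttemptData, Sequence[ParticipantRecord]],
) -> pd.DataFrame:
    data = _as_data(records)
    rows = []
    for i in np.flatnonzero(data.r == 0):
        rec = AttemptRecord(
            t=int(data.t[i]),
            email_attempted=bool(data.email[i]),
            success_attempt=None,
        )
        rows.append(
            {
                "index": int(i),
                "phone_calls": rec.t,
                "email_attempted": rec.email_attempted,
                "posterior_abstention": posterior_abstention(params, rec, data.X[i]),
            }
        )
    return pd.DataFrame(rows)


def marginal_nonresponse_abstention(
    fit: FitResult,
    records: Union[AttemptData, Sequence[ParticipantRecord]],
) -> float:
    """Unweighted mean of the posterior abstention probability over all
    nonresponders, at the fitted parameters."""
    if not isinstance(fit.params, AttemptParams):
        raise DataValidationError("fit must come from the attempts model")
    if not fit.converged:
        raise DegenerateDataError("fit did not converge; marginal prediction unreliable")
    table = _nonresponder_posteriors(fit.params, records)
    if table.empty:
        raise DegenerateDataError("no nonresponders in the data")
    return float(table["posterior_abstention"].mean())


def beta2_band(
    fit: FitResult,
    records: Union[AttemptData, Sequence[ParticipantRecord]],
    k: float = 2.0,
) -> tuple[float, float]:
    """Marginal nonresponder abstention recomputed with beta2 fixed at its
    estimate +/- k standard errors, all other parameters held at their
    estimates.  Returns (low, high): low at beta2 + k*SE (the posterior is
    decreasing in beta2), high at beta2 - k*SE."""
    se = fit.se_of("beta2")
    if not np.isfinite(se):
        raise DegenerateDataError("standard error of beta2 undefined")
    b2 = fit.estimate("beta2")
    data = _as_data(records)
    low_fit = replace(fit, params=replace(fit.params, beta2=b2 + k * se))
    high_fit = replace(fit, params=replace(fit.params, beta2=b2 - k * se))
    low = marginal_nonresponse_abstention(low_fit, data)
    high = marginal_nonresponse_abstention(high_fit, data)
    return low, high


def posterior_table(
    fit: FitResult,
    records: Union[AttemptData, Sequence[ParticipantRecord]],
) -> pd.DataFrame:
    """Per-nonresponder posterior abstention probabilities (serialisable)."""
    if not isinstance(fit.params, AttemptParams):
        raise DataValidationError("fit must come from the attempts model")
    return _nonresponder_posteriors(fit.params, records)
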