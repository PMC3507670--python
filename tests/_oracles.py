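"""Independent brute-force oracles used to validate likelihood code.

Everything here is deliberately naive: per-record Python loops, explicit
enumeration over the unobserved outcome, direct exp/(1+exp) arithmetic.
These implementations never call the package's likelihood routines.
"""

from __future__ import annotations

import math

import numpy as np


def invlogit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def brute_selection_loglik(params, records) -> float:
    """Enumerate y in {0,1} per nonresponder; direct products otherwise."""
    total = 0.0
    for rec in records:
        p1 = invlogit(params.alpha0 + float(rec.x @ params.alpha1))

        def p_y(y: int) -> float:
            return p1 if y == 1 else 1.0 - p1

        def p_resp(y: int) -> float:
            return invlogit(
                params.beta0 + float(rec.x @ params.beta1) + params.beta2 * y
            )

        if rec.r == 1:
            total += math.log(p_y(rec.y) * p_resp(rec.y))
        else:
            total += math.log(sum(p_y(y) * (1.0 - p_resp(y)) for y in (0, 1)))
    return total


def brute_attempts_loglik(params, records) -> float:
    """Four-branch enumeration over attempt histories and unobserved y."""
    total = 0.0
    for rec in records:
        p1 = invlogit(params.alpha0 + float(rec.x @ params.alpha1))

        def p_y(y: int) -> float:
            return p1 if y == 1 else 1.0 - p1

        def q(m: int, y: int) -> float:
            eta = params.beta0_m[m - 1] + float(rec.x @ params.beta1) + params.beta2 * y
            if m == 11:
                eta += params.gamma_email_calls * rec.attempts.t
            return invlogit(eta)

        def history_prob(y: int) -> float:
            prob = 1.0  # empty product is one
            for m in rec.attempts.attempts_made:
                if rec.attempts.success_attempt == m:
                    prob *= q(m, y)
                else:
                    prob *= 1.0 - q(m, y)
            return prob

        if rec.r == 1:
            total += math.log(p_y(rec.y) * history_prob(rec.y))
        else:
            total += math.log(sum(p_y(y) * history_prob(y) for y in (0, 1)))
    return total


def brute_posterior_abstention(params, attempts, x) -> float:
    """P(Y=1 | all attempts failed, x) by direct joint-probability ratio."""
    p1 = invlogit(params.alpha0 + float(x @ params.alpha1))

    def fail_prob(y: int) -> float:
        prob = 1.0
        for m in attempts.attempts_made:
            eta = params.beta0_m[m - 1] + float(x @ params.beta1) + params.beta2 * y
            if m == 11:
                eta += params.gamma_email_calls * attempts.t
            prob *= 1.0 - invlogit(eta)
        return prob

    joint1 = p1 * fail_prob(1)
    joint0 = (1.0 - p1) * fail_prob(0)
    return joint1 / (joint1 + joint0)


def random_toy_records(rng: np.random.Generator, n: int):
    """Small random cohort exercising all four likelihood branches."""
    from misstrial.core_data import AttemptRecord, ParticipantRecord

    records = []
    for i in range(n):
        x = np.array(
            [
                rng.integers(0, 2),
                float(rng.integers(20, 61)),
                rng.integers(0, 2),
                rng.integers(1, 6),
                rng.integers(0, 6),
                1.0 + 0.25 * rng.integers(0, 17),
                rng.integers(1, 6),
                rng.integers(1, 6),
                rng.integers(1, 9),
                rng.integers(0, 2),
            ],
            dtype=float,
        )
        t = int(rng.integers(1, 11))
        branch = rng.integers(0, 4)
        if branch == 0:  # phone responder
            attempts = AttemptRecord(t=t, email_attempted=False, success_attempt=t)
            y = int(rng.integers(0, 2))
        elif branch == 1:  # email responder
            attempts = AttemptRecord(t=t, email_attempted=True, success_attempt=11)
            y = int(rng.integers(0, 2))
        elif branch == 2:  # email nonresponder
            attempts = AttemptRecord(t=t, email_attempted=True, success_attempt=None)
            y = None
        else:  # phone-only nonresponder
            attempts = AttemptRecord(t=t, email_attempted=False, success_attempt=None)
            y = None
        records.append(
            ParticipantRecord(
                id=f"T{i}", x=x, y=y, r=int(y is not None), attempts=attempts
            )
        )
    return records


def random_selection_params(rng: np.random.Generator, k: int = 10, scale: float = 0.08):
    from misstrial.selection import SelectionParams

    return SelectionParams(
        alpha0=float(rng.normal(0, 0.5)),
        alpha1=rng.normal(0, scale, k),
        beta0=float(rng.normal(0, 0.5)),
        beta1=rng.normal(0, scale, k),
        beta2=float(rng.normal(0, 1.0)),
    )


def random_attempt_params(rng: np.random.Generator, k: int = 10, scale: float = 0.08):
    from misstrial.attempts import AttemptParams

    return AttemptParams(
        alpha0=float(rng.normal(0, 0.5)),
        alpha1=rng.normal(0, scale, k),
        beta0_m=rng.normal(-1.0, 0.5, 11),
        beta1=rng.normal(0, scale, k),
        beta2=float(rng.normal(0, 1.0)),
        gamma_email_calls=float(rng.normal(0, 0.05)) if rng.random() < 0.5 else 0.0,
    )
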