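"""Domain types, delimited-text I/O, validation and packaged fixture tables.

The participant-level data model is a binary trial outcome that may be
missing, a response indicator, ten complete baseline covariates in a fixed
order, and a contact-attempt history (up to ten phone calls, optionally
followed by a single email attempt, indexed as attempt 11).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, FixtureError

#: Fixed covariate order; coefficient vectors are indexed in this order.
COVARIATES: tuple[str, ...] = (
    "treatment",
    "age",
    "sex",
    "qualifications",
    "deprivation",
    "conscientiousness",
    "determination",
    "support",
    "dependence",
    "previous",
)

#: Covariates considered directly related to smoking behaviour.
SMOKING_RELATED: tuple[str, ...] = ("determination", "support", "dependence", "previous")

#: Ordinal-score covariates stored as numeric and modelled as continuous.
CATEGORICAL_COVARIATES: tuple[str, ...] = (
    "qualifications",
    "deprivation",
    "determination",
    "support",
    "dependence",
)

#: Truly continuous covariates (candidates for quadratic-term checks).
CONTINUOUS_COVARIATES: tuple[str, ...] = ("age", "conscientiousness")

BINARY_COVARIATES: tuple[str, ...] = ("treatment", "sex", "previous")

#: Attempt index reserved for the email attempt.
EMAIL_ATTEMPT = 11
MAX_PHONE_CALLS = 10

#: Tokens accepted as a missing outcome on input; empty string written out.
MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class AttemptRecord:
    """History of the attempts made to obtain a participant's outcome.

    Parameters
    ----------
    t : int
        Number of phone calls actually made, ``1 <= t <= 10``.
    email_attempted : bool
        Whether a final email attempt was made after all calls failed.
    success_attempt : int or None
        Index of the successful attempt: ``1..10`` for a phone call,
        ``11`` for the email, or ``None`` if every attempt failed.
    """

    t: int
    email_attempted: bool
    success_attempt: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.t <= MAX_PHONE_CALLS:
            raise DataValidationError(
                f"phone-call count t={self.t} outside 1..{MAX_PHONE_CALLS}"
            )
        s = self.success_attempt
        if s is not None:
            if s <= MAX_PHONE_CALLS:
                if s != self.t:
                    raise DataValidationError(
                        f"phone success at attempt {s} but t={self.t}; calls stop at success"
                    )
                if self.email_attempted:
                    raise DataValidationError(
                        "email attempted although a phone call succeeded"
                    )
            elif s == EMAIL_ATTEMPT:
                if not self.email_attempted:
                    raise DataValidationError("success at email attempt but email_attempted=False")
            else:
                raise DataValidationError(f"invalid success_attempt {s}")

    @property
    def responded(self) -> bool:
        return self.success_attempt is not None

    @property
    def attempts_made(self) -> tuple[int, ...]:
        """Indices of all attempts made, in order (phones then email)."""
        made = tuple(range(1, self.t + 1))
        if self.email_attempted:
            made += (EMAIL_ATTEMPT,)
        return made


@dataclass(frozen=True)
class ParticipantRecord:
    """One trial participant: covariates, (possibly missing) outcome and
    response indicator, plus the attempt history.

    Invariants: ``r == 1`` iff ``y`` is non-missing; all ten covariates
    present (complete baseline data); binary covariates in {0, 1}; age > 0;
    ``r`` consistent with the attempt history.
    """

    id: str
    x: np.ndarray
    y: Optional[int]
    r: int
    attempts: AttemptRecord

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.shape != (len(COVARIATES),):
            raise DataValidationError(
                f"participant {self.id}: expected {len(COVARIATES)} covariates, got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise DataValidationError(
                f"participant {self.id}: missing/non-finite covariate value "
                "(baseline covariates must be complete)"
            )
        for name in BINARY_COVARIATES:
            v = x[COVARIATES.index(name)]
            if v not in (0.0, 1.0):
                raise DataValidationError(
                    f"participant {self.id}: binary covariate {name}={v} not in {{0,1}}"
                )
        if x[COVARIATES.index("age")] <= 0:
            raise DataValidationError(f"participant {self.id}: age must be positive")
        if self.r not in (0, 1):
            raise DataValidationError(f"participant {self.id}: r must be 0/1")
        if (self.y is not None) != (self.r == 1):
            raise DataValidationError(
                f"participant {self.id}: inconsistent response indicator "
                "(r=1 iff outcome observed)"
            )
        if self.y is not None and self.y not in (0, 1):
            raise DataValidationError(f"participant {self.id}: outcome must be 0/1 or missing")
        if self.attempts.responded != (self.r == 1):
            raise DataValidationError(
                f"participant {self.id}: response indicator disagrees with attempt history"
            )


@dataclass(frozen=True)
class MissingnessSummary:
    """Counts of outcome status by trial arm (layout of a 3x2 count table:
    not-abstained / abstained / missing, by treatment and control)."""

    by_arm: Mapping[str, Mapping[str, int]]

    ARMS = ("treatment", "control")
    STATUSES = ("not_abstained", "abstained", "missing")

    def count(self, status: str, arm: Optional[str] = None) -> int:
        if arm is not None:
            return int(self.by_arm[arm][status])
        return sum(int(self.by_arm[a][status]) for a in self.ARMS)

    @property
    def n_total(self) -> int:
        return sum(self.count(s) for s in self.STATUSES)

    @property
    def n_missing(self) -> int:
        return self.count("missing")

    @property
    def n_abstained(self) -> int:
        return self.count("abstained")

    @property
    def n_not_abstained(self) -> int:
        return self.count("not_abstained")

    @property
    def n_responders(self) -> int:
        return self.n_abstained + self.n_not_abstained

    @property
    def prop_missing(self) -> float:
        """Fraction of participants with a missing outcome."""
        return self.n_missing / self.n_total

    @property
    def responder_abstention(self) -> float:
        """Complete-case abstention rate P(Y=1 | R=1)."""
        return self.n_abstained / self.n_responders

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {arm: [self.by_arm[arm][s] for s in self.STATUSES] for arm in self.ARMS},
            index=list(self.STATUSES),
        )


@dataclass(frozen=True)
class AttemptSummaryTable:
    """Counts of participants, responders and quitters by
    (phone-call count, email-attempted) cell."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("phone_calls", "email", "participants", "responders", "quitters")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataValidationError(f"attempt summary missing columns {missing}")
        if (df["responders"] > df["participants"]).any():
            raise DataValidationError("responders exceed participants in some cell")
        if (df["quitters"] > df["responders"]).any():
            raise DataValidationError("quitters exceed responders in some cell")

    @property
    def n_participants(self) -> int:
        return int(self.table["participants"].sum())

    @property
    def n_responders(self) -> int:
        return int(self.table["responders"].sum())

    @property
    def n_quitters(self) -> int:
        return int(self.table["quitters"].sum())

    def phone_responder_rows(self) -> pd.DataFrame:
        """Rows of participants contacted by phone only (no email attempt);
        their responders answered a phone call."""
        return self.table[self.table["email"] == 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O

_CANONICAL_COLUMNS = (
    ("id",)
    + COVARIATES
    + ("outcome", "phone_calls", "email_attempted", "success_attempt")
)


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        f = float(value)
    except ValueError as exc:
        raise DataValidationError(f"row {row}: non-numeric {column}={value!r}") from exc
    if f != int(f):
        raise DataValidationError(f"row {row}: non-integer {column}={value!r}")
    return int(f)


def read_trial_table(
    path, schema: Optional[Mapping[str, str]] = None
) -> list[ParticipantRecord]:
    """Read a delimited participant table into validated records.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    schema : mapping, optional
        Maps canonical column names (``id``, the ten covariates, ``outcome``,
        ``phone_calls``, ``email_attempted``, ``success_attempt``) to the
        file's actual column names.

    The outcome column may be empty or ``NA`` for a missing outcome; an empty
    ``success_attempt`` means no attempt succeeded. Row order is preserved.
    """
    colmap = {c: c for c in _CANONICAL_COLUMNS}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [colmap[c] for c in _CANONICAL_COLUMNS if colmap[c] not in df.columns]
    if missing_cols:
        raise DataValidationError(f"missing required column(s): {missing_cols}")

    records: list[ParticipantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        get = lambda c: row_d[colmap[c]].strip()  # noqa: E731
        for cov in COVARIATES:
            if get(cov) in MISSING_TOKENS:
                raise DataValidationError(
                    f"row {i}: covariate {cov} is missing; baseline covariates must be complete"
                )
        x = np.array([float(get(cov)) for cov in COVARIATES])
        out_raw = get("outcome")
        y = None if out_raw in MISSING_TOKENS else _parse_int(out_raw, "outcome", i)
        r = 0 if y is None else 1
        t = _parse_int(get("phone_calls"), "phone_calls", i)
        email_raw = get("email_attempted").lower()
        email = email_raw in ("1", "true", "yes")
        succ_raw = get("success_attempt")
        succ = None if succ_raw in MISSING_TOKENS else _parse_int(succ_raw, "success_attempt", i)
        if (succ is not None) != (r == 1):
            raise DataValidationError(f"row {i}: inconsistent response indicator")
        attempts = AttemptRecord(t=t, email_attempted=email, success_attempt=succ)
        records.append(ParticipantRecord(id=get("id"), x=x, y=y, r=r, attempts=attempts))
    return records


def write_trial_table(records: Iterable[ParticipantRecord], path) -> None:
    """Write records as CSV with the canonical columns; missing outcome and
    absent success are written as empty fields."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CANONICAL_COLUMNS)
        for rec in records:
            xvals = [
                str(int(v)) if float(v).is_integer() else repr(float(v)) for v in rec.x
            ]
            writer.writerow(
                [rec.id]
                + xvals
                + [
                    "" if rec.y is None else str(rec.y),
                    str(rec.attempts.t),
                    str(int(rec.attempts.email_attempted)),
                    "" if rec.attempts.success_attempt is None
                    else str(rec.attempts.success_attempt),
                ]
            )


def summarize_missingness(records: Sequence[ParticipantRecord]) -> MissingnessSummary:
    """Tabulate outcome status (not abstained / abstained / missing) by arm."""
    if len(records) == 0:
        raise DataValidationError("no records to summarise")
    counts = {arm: {s: 0 for s in MissingnessSummary.STATUSES} for arm in MissingnessSummary.ARMS}
    i_treat = COVARIATES.index("treatment")
    for rec in records:
        arm = "treatment" if rec.x[i_treat] == 1 else "control"
        if rec.y is None:
            counts[arm]["missing"] += 1
        elif rec.y == 1:
            counts[arm]["abstained"] += 1
        else:
            counts[arm]["not_abstained"] += 1
    return MissingnessSummary(by_arm=counts)


def load_fixture(name: str) -> Union[MissingnessSummary, AttemptSummaryTable]:
    """Load a packaged count-table fixture.

    ``"table1"`` gives the outcome-missingness pattern by arm as a
    :class:`MissingnessSummary`; ``"table3"`` gives outcome counts by number
    and type of contact attempts as an :class:`AttemptSummaryTable`.
    """
    base = resources.files(__package__) / "fixtures"
    if name == "table1":
        df = pd.read_csv(base / "table1.csv", index_col="status")
        by_arm = {
            arm: {s: int(df.loc[s, arm]) for s in MissingnessSummary.STATUSES}
            for arm in MissingnessSummary.ARMS
        }
        return MissingnessSummary(by_arm=by_arm)
    if name == "table3":
        return AttemptSummaryTable(table=pd.read_csv(base / "table3.csv"))
    raise FixtureError(f"unknown fixture {name!r}; available: 'table1', 'table3'")
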