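"""Partial calendar dates and time-to-onset arithmetic.

Spontaneous reports often carry incomplete dates (year only, or year and
month).  Incomplete dates are completed deterministically before computing
the time to onset (TTO): a missing day becomes the 15th (middle of the
month); a missing month and day become July 2 (middle of the year).  When
completion produces a negative TTO the value is discarded rather than
clamped, since the sign is then an artefact of imputation.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PartialDate",
    "NotImputableError",
    "impute_date",
    "compute_tto",
    "impute_ymd_arrays",
]

IMPUTED_DAY = 15
IMPUTED_MONTH = 7
IMPUTED_MIDYEAR_DAY = 2


class NotImputableError(ValueError):
    """Raised when a date is absent entirely and cannot be completed."""


@dataclass(frozen=True)
class PartialDate:
    """A calendar date in which month and day may be unknown.

    Invariants: ``day`` may only be present when ``month`` is, and a
    complete triple must form a valid calendar date.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # raises ValueError for impossible dates such as Feb 30
            datetime.date(self.year, self.month, self.day)

    @property
    def complete(self) -> bool:
        return self.month is not None and self.day is not None


def impute_date(pdate: PartialDate | None) -> datetime.date:
    """Complete a partial date: missing day -> 15th, missing month -> July 2.

    Raises :class:`NotImputableError` if the date is absent entirely
    (``None``); the caller then treats the associated TTO as missing.
    """
    if pdate is None:
        raise NotImputableError("date absent entirely")
    if pdate.month is None:
        return datetime.date(pdate.year, IMPUTED_MONTH, IMPUTED_MIDYEAR_DAY)
    if pdate.day is None:
        return datetime.date(pdate.year, pdate.month, IMPUTED_DAY)
    return datetime.date(pdate.year, pdate.month, pdate.day)


def compute_tto(start: PartialDate | None, onset: PartialDate | None) -> int | None:
    """Days from drug start to event onset, or ``None`` when unavailable.

    Either date missing -> ``None``.  A negative difference after
    imputation -> ``None`` (imputation artefact).  Same-day start and
    onset yields 0, which is kept.
    """
    try:
        d_start = impute_date(start)
        d_onset = impute_date(onset)
    except NotImputableError:
        return None
    delta = (d_onset - d_start).days
    if delta < 0:
        return None
    return delta


def impute_ymd_arrays(
    year: pd.Series | np.ndarray,
    month: pd.Series | np.ndarray,
    day: pd.Series | np.ndarray,
) -> pd.Series:
    """Vectorised date completion over year/month/day columns.

    Missing components are encoded as NaN.  Rows with a missing year give
    NaT.  Applies the same rules as :func:`impute_date`.
    """
    y = pd.to_numeric(pd.Series(year).reset_index(drop=True), errors="coerce")
    m = pd.to_numeric(pd.Series(month).reset_index(drop=True), errors="coerce")
    d = pd.to_numeric(pd.Series(day).reset_index(drop=True), errors="coerce")

    no_month = m.isna()
    no_day = d.isna()
    m = m.where(~no_month, IMPUTED_MONTH)
    d = d.where(~(no_day & ~no_month), IMPUTED_DAY)
    d = d.where(~no_month, IMPUTED_MIDYEAR_DAY)

    frame = pd.DataFrame({"year": y, "month": m, "day": d})
    return pd.to_datetime(frame, errors="coerce")
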