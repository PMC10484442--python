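"""Prescribed average daily dose (ADD) computation.

A dosing regimen prescribes ``n`` component (dose, frequency) pairs to be
taken within a repeating interval of ``t`` hours.  The prescribed average
daily dose is

    ADD = (1 / t_days) * sum_i d_i * f_i

i.e. the total dose delivered over one interval, normalised per day.  The
ADD captures the prescriber's intended treatment plan, not the administered
amount.

Prescriptions come in four types: *scheduled* (numeric ADD), *one-time*
(a single administration — excluded from longitudinal analysis), *PN*
("pro necessitata", as needed) and *VAO* (variable dose, e.g. insulin
titrated on blood glucose); the latter two receive a categorical ADD.

Missing regimen fields are filled by a fixed default cascade (dose from
package strength x volume; volume 1; interval derived from frequency;
daily interval; frequency 1); every applied default is recorded so that
downstream exclusions are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

HOURS_PER_DAY = 24.0

#: significant digits used when comparing ADD values downstream; dosage
#: values are human-entered decimals, so float noise must not register as
#: a dosage change.
ADD_SIG_DIGITS = 6

#: mass-unit conversion factors to milligrams; sequences mixing units
#: outside this table cannot be compared and are excluded.
UNIT_TO_MG = {
    "g": 1000.0,
    "mg": 1.0,
    "mcg": 0.001,
    "ug": 0.001,
}


class RxType(str, Enum):
    """Prescription type."""

    ONE_TIME = "one-time"
    SCHEDULED = "scheduled"
    PN = "PN"
    VAO = "VAO"


class AddKind(str, Enum):
    """Classification of a computed ADD."""

    NUMERIC = "numeric"
    PN = "PN"
    VAO = "VAO"
    EXCLUDED = "excluded"


class DataError(ValueError):
    """A prescription row violates basic data constraints."""


@dataclass(frozen=True)
class Regimen:
    """A dosing regimen: components (dose d_i, frequency f_i) over an
    interval of ``interval_hours`` hours."""

    components: tuple[tuple[float, int], ...]
    interval_hours: float
    unit: str = "mg"

    def __post_init__(self) -> None:
        if self.interval_hours <= 0:
            raise DataError(f"non-positive interval: {self.interval_hours}")
        for d, f in self.components:
            if d < 0:
                raise DataError(f"negative dose: {d}")
            if f < 1:
                raise DataError(f"frequency below 1: {f}")


@dataclass(frozen=True)
class Prescription:
    """One timestamped drug order.

    ``dose``/``freq``/``interval_hours`` may be missing (None); the default
    cascade fills them where possible.  ``components`` overrides
    ``dose``/``freq`` for multi-component regimens.
    """

    drug: str
    rx_type: RxType
    start: float = 0.0
    end: float = 0.0
    dose: Optional[float] = None
    freq: Optional[int] = None
    interval_hours: Optional[float] = None
    strength: Optional[float] = None
    volume: Optional[float] = None
    unit: str = "mg"
    components: Optional[tuple[tuple[float, int], ...]] = None
    rx_id: Optional[str] = None


@dataclass(frozen=True)
class AddResult:
    """Computed ADD for one prescription."""

    kind: AddKind
    value: Optional[float] = None
    unit: Optional[str] = None
    applied_defaults: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if (self.kind is AddKind.NUMERIC) != (self.value is not None):
            raise ValueError("numeric kind iff value present")


def round_sig(x: float, digits: int = ADD_SIG_DIGITS) -> float:
    """Round ``x`` to ``digits`` significant digits (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def regimen_add(regimen: Regimen) -> float:
    """Numeric ADD of a fully specified regimen (per day)."""
    t_days = regimen.interval_hours / HOURS_PER_DAY
    total = sum(d * f for d, f in regimen.components)
    return total / t_days


def compute_add(rx: Prescription) -> AddResult:
    """Compute the ADD for one prescription, applying the default cascade.

    Cascade order when fields are missing: dose from package strength x
    prescribed volume; volume assumed 1; interval derived from frequency;
    daily interval assumed; frequency assumed 1.  PN/VAO prescriptions get
    a categorical ADD; one-time prescriptions and prescriptions whose ADD
    remains incomputable are excluded.
    """
    if rx.rx_type is RxType.PN:
        return AddResult(AddKind.PN)
    if rx.rx_type is RxType.VAO:
        return AddResult(AddKind.VAO)
    if rx.rx_type is RxType.ONE_TIME:
        return AddResult(AddKind.EXCLUDED)

    defaults: set[str] = set()

    if rx.components is not None:
        components = list(rx.components)
    else:
        dose = rx.dose
        if dose is None:
            if rx.strength is not None:
                volume = rx.volume
                if volume is None:
                    volume = 1.0
                    defaults.add("volume=1")
                dose = rx.strength * volume
                defaults.add("dose-from-strength")
            else:
                return AddResult(AddKind.EXCLUDED, applied_defaults=frozenset(defaults))
        freq = rx.freq
        if freq is None:
            freq = 1
            defaults.add("freq=1")
        components = [(float(dose), int(freq))]

    interval = rx.interval_hours
    if interval is None:
        # a stated frequency without an interval implies a daily pattern;
        # with neither stated, a daily interval is assumed outright
        if rx.freq is not None or rx.components is not None:
            interval = HOURS_PER_DAY
            defaults.add("interval-from-frequency")
        else:
            interval = HOURS_PER_DAY
            defaults.add("daily-interval")

    row = rx.rx_id or rx.drug
    if interval <= 0:
        raise DataError(f"non-positive interval in prescription {row!r}: {interval}")
    for d, f in components:
        if d < 0:
            raise DataError(f"negative dose in prescription {row!r}: {d}")
        if f < 1:
            raise DataError(f"frequency below 1 in prescription {row!r}: {f}")

    value = regimen_add(Regimen(tuple(components), interval, rx.unit))
    return AddResult(AddKind.NUMERIC, value=value, unit=rx.unit,
                     applied_defaults=frozenset(defaults))


@dataclass(frozen=True)
class AddSequence:
    """Ordered ADD results for one drug's prescriptions in one admission."""

    results: tuple[AddResult, ...]
    complete: bool
    #: numeric ADD values converted to a common unit (mg) and rounded;
    #: only meaningful when ``complete``.
    values: tuple[float, ...] = ()


def add_sequence(prescriptions: Sequence[Prescription]) -> AddSequence:
    """Compute the ordered ADD sequence for time-ordered prescriptions of
    one drug, flagging the sequence incomplete if any element is
    non-numeric or units cannot be reconciled."""
    starts = [p.start for p in prescriptions]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("prescriptions must be time-ordered")
    results = tuple(compute_add(p) for p in prescriptions)
    complete = all(r.kind is AddKind.NUMERIC for r in results)
    values: tuple[float, ...] = ()
    if complete and results:
        units = [r.unit or "mg" for r in results]
        if any(u not in UNIT_TO_MG for u in units):
            complete = False
        else:
            values = tuple(
                round_sig(r.value * UNIT_TO_MG[u]) for r, u in zip(results, units)
            )
    return AddSequence(results, complete, values)


# ---------------------------------------------------------------------------
# table interface

#: columns expected in prescriptions.tsv
PRESCRIPTION_COLUMNS = [
    "rx_id", "admission_id", "patient_id", "drug_atc", "start", "end",
    "dose", "unit", "freq", "interval_hours", "rx_type", "strength", "volume",
]


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def compute_add_frame(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Compute ADD for every row of a prescriptions table.

    Returns a frame keyed by ``rx_id`` with columns ``add_kind``,
    ``add_value`` (NaN when categorical/excluded), ``add_unit`` and
    ``applied_defaults`` (comma-joined).
    """
    records = []
    for row in prescriptions.itertuples(index=False):
        rx = Prescription(
            drug=row.drug_atc,
            rx_type=RxType(row.rx_type),
            start=float(row.start),
            end=float(row.end),
            dose=_opt(row.dose),
            freq=None if pd.isna(row.freq) else int(row.freq),
            interval_hours=_opt(row.interval_hours),
            strength=_opt(getattr(row, "strength", np.nan)),
            volume=_opt(getattr(row, "volume", np.nan)),
            unit=row.unit if isinstance(row.unit, str) else "mg",
            rx_id=str(row.rx_id),
        )
        res = compute_add(rx)
        records.append(
            {
                "rx_id": str(row.rx_id),
                "add_kind": res.kind.value,
                "add_value": np.nan if res.value is None else res.value,
                "add_unit": res.unit or "",
                "applied_defaults": ",".join(sorted(res.applied_defaults)),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["rx_id", "add_kind", "add_value", "add_unit", "applied_defaults"]
    )
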