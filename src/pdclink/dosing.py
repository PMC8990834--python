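"""Dose-instruction parsing and the prescribed → carried-forward → standard
fallback chain.

Every dispensing event must end up with exactly one daily dose before
coverage can be computed. The resolution order is:

1. the event's own free-text instruction, if it parses (provenance
   ``prescribed``);
2. otherwise the most recent earlier parseable instruction for the *same
   patient and same product* (provenance ``carried_forward``);
3. otherwise the product's standard daily dose (provenance ``standard``).

When an instruction prescribes a range ("1-2 puffs twice daily") the mean of
the range is used, so that example resolves to 3 dose units/day. Doses are
abstract "dose units per day" (actuations, tablets); no mass conversion is
attempted because coverage arithmetic only needs doses-per-day against
doses-per-pack.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DoseParseError
from .records import Catalog, DispensingEvent

logger = logging.getLogger(__name__)

PRESCRIBED = "prescribed"
CARRIED_FORWARD = "carried_forward"
STANDARD = "standard"
PROVENANCES = (PRESCRIBED, CARRIED_FORWARD, STANDARD)


@dataclass(frozen=True)
class DoseRegimen:
    """A resolved daily dose with its provenance.

    ``daily_dose`` is the mean of the per-administration range times the
    administration frequency.
    """

    min_per_admin: float
    max_per_admin: float
    admins_per_day: float
    provenance: str

    def __post_init__(self) -> None:
        if self.min_per_admin <= 0 or self.max_per_admin <= 0:
            raise ValueError("per-administration doses must be positive")
        if self.min_per_admin > self.max_per_admin:
            raise ValueError("min_per_admin must not exceed max_per_admin")
        if self.admins_per_day <= 0:
            raise ValueError("admins_per_day must be positive")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def daily_dose(self) -> float:
        return (self.min_per_admin + self.max_per_admin) / 2.0 * self.admins_per_day

    def carried(self) -> "DoseRegimen":
        return DoseRegimen(
            self.min_per_admin, self.max_per_admin, self.admins_per_day, CARRIED_FORWARD
        )

    @classmethod
    def standard_for(cls, daily_dose: float) -> "DoseRegimen":
        return cls(daily_dose, daily_dose, 1.0, STANDARD)


_FREQUENCIES = {
    "once daily": 1.0,
    "every morning": 1.0,
    "every night": 1.0,
    "mane": 1.0,
    "nocte": 1.0,
    "twice daily": 2.0,
    "bd": 2.0,
    "three times daily": 3.0,
    "tds": 3.0,
    "four times daily": 4.0,
    "qid": 4.0,
}

_UNITS = r"puffs?|inhalations?|tablets?|doses?"

_INSTRUCTION_RE = re.compile(
    r"^\s*(?P<min>\d+(?:\.\d+)?)\s*(?:-\s*(?P<max>\d+(?:\.\d+)?))?\s*"
    rf"(?:{_UNITS})\s+(?P<freq>{'|'.join(re.escape(f) for f in _FREQUENCIES)})\s*$",
    re.IGNORECASE,
)


def parse_dose_instruction(text: str) -> DoseRegimen:
    """Parse a free-text instruction such as ``"1-2 puffs twice daily"``.

    Grammar: ``<n>[-<m>] <unit> <frequency>`` with unit one of
    puff/inhalation/tablet/dose (optionally plural) and frequency one of
    once/twice/three times/four times daily, mane, nocte, bd, tds, qid,
    every morning, every night. Case-insensitive.

    Raises :class:`DoseParseError` (carrying the raw text) on anything else —
    never a silent default.
    """
    if text is None:
        raise DoseParseError("")
    m = _INSTRUCTION_RE.match(text)
    if not m:
        raise DoseParseError(text)
    lo = float(m.group("min"))
    hi = float(m.group("max")) if m.group("max") else lo
    if lo <= 0 or hi < lo:
        raise DoseParseError(text)
    return DoseRegimen(lo, hi, _FREQUENCIES[m.group("freq").lower()], PRESCRIBED)


def try_parse_dose_instruction(text: Optional[str]) -> Optional[DoseRegimen]:
    """Like :func:`parse_dose_instruction` but returns None on failure."""
    if text is None:
        return None
    try:
        return parse_dose_instruction(text)
    except DoseParseError:
        return None


@dataclass(frozen=True)
class ResolvedEvent:
    """A dispensing event annotated with its resolved dose regimen."""

    event: DispensingEvent
    regimen: DoseRegimen

    @property
    def daily_dose(self) -> float:
        return self.regimen.daily_dose


def resolve_doses(
    events: Iterable[DispensingEvent], catalog: Catalog
) -> list[ResolvedEvent]:
    """Assign every event a daily dose via the three-step fallback chain.

    Carry-forward is scoped to (patient, product) and never reaches backward
    in time: an event's regimen depends only on instructions dated on or
    before its supply date. When two same-day instructions exist for one
    product the later one in input order wins. Unparseable but non-empty
    instructions are treated as absent (the fallback chain applies) and
    logged.

    Works identically for a pure pharmacy stream and for a merged
    claims+pharmacy stream: merged claims-only events carry no instruction
    and inherit via carry-forward or the standard dose.
    """
    indexed = list(enumerate(events))
    indexed.sort(key=lambda ie: (ie[1].patient_id, ie[1].product_code,
                                 ie[1].supply_date, ie[0]))
    resolved: list[ResolvedEvent] = []
    last: dict[tuple[str, str], DoseRegimen] = {}
    n_unparseable = 0
    for _, ev in indexed:
        key = (ev.patient_id, ev.product_code)
        regimen = try_parse_dose_instruction(ev.dose_instruction)
        if regimen is None and ev.dose_instruction:
            n_unparseable += 1
            logger.warning(
                "unparseable instruction %r (%s, %s, %s); falling back",
                ev.dose_instruction, ev.patient_id, ev.product_code, ev.supply_date,
            )
        if regimen is not None:
            last[key] = regimen
        elif key in last:
            regimen = last[key].carried()
        else:
            regimen = DoseRegimen.standard_for(
                catalog[ev.product_code].standard_daily_dose
            )
        resolved.append(ResolvedEvent(ev, regimen))
    if n_unparseable:
        logger.info("resolve_doses: %d unparseable instructions", n_unparseable)
    return resolved


def provenance_counts(resolved: Iterable[ResolvedEvent]) -> Counter:
    """How many events resolved via each provenance (partition of all events)."""
    return Counter(r.regimen.provenance for r in resolved)


def resolution_report(resolved: Sequence[ResolvedEvent]) -> pd.DataFrame:
    """Audit table: per event the chosen daily dose, provenance and raw text."""
    return pd.DataFrame(
        {
            "patient_id": [r.event.patient_id for r in resolved],
            "product_code": [r.event.product_code for r in resolved],
            "supply_date": [r.event.supply_date.isoformat() for r in resolved],
            "source": [r.event.source for r in resolved],
            "raw_instruction": [r.event.dose_instruction or "" for r in resolved],
            "daily_dose": [r.daily_dose for r in resolved],
            "provenance": [r.regimen.provenance for r in resolved],
        }
    )
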