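"""Coverage intervals, refill-overlap adjustment, and PDC.

The proportion of days covered (PDC) is

    PDC (%) = 100 x (days with medication available) / (days in the period),

counted over a half-open observation window of whole calendar days
(default 365). "Available" means at least one controller product's supply
covers the day.

Each fill supplies ``floor(quantity x doses_per_pack / daily_dose)`` days
(minimum 1). When a refill is granted before the previous supply of the
same product runs out, its coverage start is shifted to the day the
previous supply ends, so overlapping supplies extend coverage rather than
overwrite it (full stockpile carryover within a product). Stockpiling does
not chain across different products; their intervals simply union.

Three data-source regimes are supported:

* ``claims_only`` — claims events, standard daily doses (claims data carry
  no prescribed dose);
* ``pharmacy_only`` — pharmacy events with the prescribed → carried-forward
  → standard dose chain;
* ``combined`` — claims supply dates and quantities, doses inherited from
  matched pharmacy instructions via record linkage.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .dosing import ResolvedEvent, resolve_doses
from .errors import ValidationError
from .linkage import build_combined_stream, match_events
from .records import (
    Catalog,
    DispensingEvent,
    ObservationWindow,
    filter_controllers,
    sort_events,
)

logger = logging.getLogger(__name__)

REGIME_CLAIMS = "claims_only"
REGIME_PHARMACY = "pharmacy_only"
REGIME_COMBINED = "combined"
REGIMES = (REGIME_CLAIMS, REGIME_PHARMACY, REGIME_COMBINED)

DEFAULT_ADHERENCE_THRESHOLD = 80.0


@dataclass(frozen=True)
class CoverageInterval:
    """Half-open date interval [start, end_exclusive) of medication
    availability for one (patient, product)."""

    patient_id: str
    product_code: str
    start: dt.date
    end_exclusive: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end_exclusive:
            raise ValidationError(
                f"interval start {self.start} must precede end {self.end_exclusive}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_exclusive - self.start).days


def days_supplied(quantity: int, doses_per_pack: int, daily_dose: float) -> int:
    """Whole days of therapy in a fill: floor(quantity x pack / daily dose), min 1.

    Flooring is the conservative convention; a fill too small for a full day
    still grants one day (the dispensing day itself).
    """
    if daily_dose <= 0:
        raise ValidationError(f"daily_dose must be positive, got {daily_dose}")
    if quantity < 1 or doses_per_pack < 1:
        raise ValidationError("quantity and doses_per_pack must be >= 1")
    return max(1, math.floor(quantity * doses_per_pack / daily_dose))


def event_days_supplied(resolved: ResolvedEvent, catalog: Catalog) -> int:
    product = catalog[resolved.event.product_code]
    return days_supplied(
        resolved.event.quantity, product.doses_per_pack, resolved.daily_dose
    )


def adjust_overlaps(
    resolved: Sequence[ResolvedEvent], catalog: Catalog
) -> list[CoverageInterval]:
    """Build non-overlapping intervals for ONE (patient, product) fill list.

    interval_i.start = max(supply_date_i, previous interval's end);
    interval_i.end = start + days supplied. No supply is discarded: an early
    refill's days are pushed forward, never truncated.
    """
    events = sorted(resolved, key=lambda r: r.event.supply_date)
    intervals: list[CoverageInterval] = []
    prev_end: Optional[dt.date] = None
    for r in events:
        start = r.event.supply_date
        if prev_end is not None and prev_end > start:
            start = prev_end
        end = start + dt.timedelta(days=event_days_supplied(r, catalog))
        intervals.append(
            CoverageInterval(r.event.patient_id, r.event.product_code, start, end)
        )
        prev_end = end
    return intervals


def build_intervals(
    resolved: Iterable[ResolvedEvent], catalog: Catalog
) -> list[CoverageInterval]:
    """Overlap-adjusted intervals for one patient, grouped per product."""
    by_product: dict[str, list[ResolvedEvent]] = {}
    for r in resolved:
        by_product.setdefault(r.event.product_code, []).append(r)
    intervals: list[CoverageInterval] = []
    for code in sorted(by_product):
        intervals.extend(adjust_overlaps(by_product[code], catalog))
    return intervals


def covered_days(
    intervals: Iterable[CoverageInterval], window: ObservationWindow
) -> int:
    """Whole days in the window covered by the union of intervals.

    Coverage by ANY product counts once; coverage extending past the window
    end is truncated.
    """
    clipped = []
    for iv in intervals:
        start = max(iv.start, window.start_date)
        end = min(iv.end_exclusive, window.end_date)
        if start < end:
            clipped.append((start, end))
    clipped.sort()
    total = 0
    cur_start: Optional[dt.date] = None
    cur_end: Optional[dt.date] = None
    for start, end in clipped:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += (cur_end - cur_start).days
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    if cur_end is not None:
        total += (cur_end - cur_start).days
    return total


def compute_pdc(
    intervals: Iterable[CoverageInterval], window: ObservationWindow
) -> float:
    """PDC percent in [0, 100] for one patient over the window."""
    return 100.0 * covered_days(intervals, window) / window.n_days


def window_filter(
    events: Iterable[DispensingEvent], window: ObservationWindow
) -> list[DispensingEvent]:
    """Keep events whose supply date lies in the window.

    Fills dated before the window contribute no lead-in coverage (only a
    12-month history exists per patient), and fills on/after the window end
    are outside the observation period.
    """
    return [e for e in events if e.supply_date in window]


@dataclass
class RegimeOutcome:
    """One patient x regime coverage result."""

    pdc: float
    covered_days: int
    window_days: int
    n_events: int
    truncated: bool  # coverage extended past the window end


def _coverage_outcome(
    events: list[DispensingEvent], catalog: Catalog, window: ObservationWindow
) -> RegimeOutcome:
    resolved = resolve_doses(sort_events(events), catalog)
    intervals = build_intervals(resolved, catalog)
    covered = covered_days(intervals, window)
    truncated = any(iv.end_exclusive > window.end_date for iv in intervals)
    if truncated:
        logger.debug(
            "coverage truncated at window end for patient %s",
            events[0].patient_id if events else "?",
        )
    return RegimeOutcome(
        pdc=100.0 * covered / window.n_days,
        covered_days=covered,
        window_days=window.n_days,
        n_events=len(events),
        truncated=truncated,
    )


def run_regime(
    claims_events: Sequence[DispensingEvent],
    pharmacy_events: Sequence[DispensingEvent],
    regime: str,
    catalog: Catalog,
    window: ObservationWindow,
    date_tolerance_days: int = 0,
    match_quantity: bool = True,
) -> RegimeOutcome:
    """Compute one patient's coverage under one data-source regime.

    Inputs are the patient's full claims and pharmacy streams; controller
    filtering and window filtering are applied here so the three regimes see
    consistent inputs.
    """
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}")
    claims = window_filter(filter_controllers(claims_events, catalog), window)
    pharmacy = window_filter(filter_controllers(pharmacy_events, catalog), window)
    if regime == REGIME_CLAIMS:
        events = claims
    elif regime == REGIME_PHARMACY:
        events = pharmacy
    else:
        link = match_events(
            claims,
            pharmacy,
            date_tolerance_days=date_tolerance_days,
            match_quantity=match_quantity,
        )
        events = build_combined_stream(link)
    return _coverage_outcome(list(events), catalog, window)


@dataclass
class PatientAdherence:
    """Per-patient PDC triple with binary adherence flags and pharmacy-use
    class."""

    patient_id: str
    pdc_pharmacy: float
    pdc_claims: float
    pdc_combined: float
    adherent_pharmacy: bool
    adherent_claims: bool
    adherent_combined: bool
    pharmacy_use_class: str

    def __post_init__(self) -> None:
        for v in (self.pdc_pharmacy, self.pdc_claims, self.pdc_combined):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"PDC {v} outside [0, 100]")


def patient_adherence(
    patient_id: str,
    claims_events: Sequence[DispensingEvent],
    pharmacy_events: Sequence[DispensingEvent],
    catalog: Catalog,
    window: ObservationWindow,
    threshold: float = DEFAULT_ADHERENCE_THRESHOLD,
    date_tolerance_days: int = 0,
    match_quantity: bool = True,
) -> PatientAdherence:
    """All three regimes plus single/multiple classification for one patient.

    A patient is adherent under a regime iff PDC >= threshold (the 80%
    boundary is inclusive).
    """
    claims = window_filter(filter_controllers(claims_events, catalog), window)
    pharmacy = window_filter(filter_controllers(pharmacy_events, catalog), window)
    link = match_events(
        claims,
        pharmacy,
        date_tolerance_days=date_tolerance_days,
        match_quantity=match_quantity,
    )
    out_claims = _coverage_outcome(list(claims), catalog, window)
    out_pharmacy = _coverage_outcome(list(pharmacy), catalog, window)
    out_combined = _coverage_outcome(build_combined_stream(link), catalog, window)
    return PatientAdherence(
        patient_id=patient_id,
        pdc_pharmacy=out_pharmacy.pdc,
        pdc_claims=out_claims.pdc,
        pdc_combined=out_combined.pdc,
        adherent_pharmacy=out_pharmacy.pdc >= threshold,
        adherent_claims=out_claims.pdc >= threshold,
        adherent_combined=out_combined.pdc >= threshold,
        pharmacy_use_class=link.pharmacy_use_class,
    )
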