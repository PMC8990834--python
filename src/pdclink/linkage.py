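"""Claims ↔ pharmacy record matching and pharmacy-use classification.

Claims data are complete across pharmacies but dose-blind; a study
pharmacy's dispensing data carry prescribed doses but miss fills made
elsewhere. Matching the two streams per patient answers two questions:

* which claims events have a pharmacy twin (and hence a dose instruction
  to inherit), and
* whether the patient collected controller medicines from more than one
  pharmacy — any claims event with no pharmacy twin is evidence of a fill
  at a non-study pharmacy, so the patient is classified a *multiple*
  pharmacy user; otherwise *single*.

The merged ("combined") stream keeps claims as the authoritative event
list — one output event per claims event — with matched events inheriting
the pharmacy instruction.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import defaultdict, deque
from dataclasses import dataclass

import pandas as pd

from .records import DispensingEvent, sort_events, with_instruction

logger = logging.getLogger(__name__)

SINGLE = "single"
MULTIPLE = "multiple"


@dataclass
class LinkageResult:
    """Outcome of matching one patient's claims and pharmacy streams."""

    pairs: list[tuple[DispensingEvent, DispensingEvent]]
    unmatched_claims: list[DispensingEvent]
    unmatched_pharmacy: list[DispensingEvent]

    @property
    def pharmacy_use_class(self) -> str:
        return MULTIPLE if self.unmatched_claims else SINGLE

    @property
    def n_claims(self) -> int:
        return len(self.pairs) + len(self.unmatched_claims)


def match_events(
    claims: list[DispensingEvent],
    pharmacy: list[DispensingEvent],
    date_tolerance_days: int = 0,
    match_quantity: bool = True,
) -> LinkageResult:
    """Greedy one-to-one matching on (product_code, supply_date[, quantity]).

    Both inputs are one patient's controller-filtered streams. Exact-date
    matching is the default; ``date_tolerance_days`` allows a pharmacy event
    dated within ±k days to pair with a claims event (nearest date first),
    for messy exports. Each event joins at most one pair; leftovers land in
    the respective unmatched sets.
    """
    claims = sort_events(claims)
    pharmacy = sort_events(pharmacy)

    def key(e: DispensingEvent, date):
        return (e.product_code, date, e.quantity) if match_quantity else (
            e.product_code, date)

    pool: dict[tuple, deque[int]] = defaultdict(deque)
    for j, pe in enumerate(pharmacy):
        pool[key(pe, pe.supply_date)].append(j)

    used = [False] * len(pharmacy)
    partner: list[int | None] = [None] * len(claims)
    # offset-major passes: all exact-date matches first, then outward by |offset|,
    # so a tolerant match never steals an event from an exact one
    offsets = [0]
    for d in range(1, date_tolerance_days + 1):
        offsets += [-d, d]
    for off in offsets:
        for i, ce in enumerate(claims):
            if partner[i] is not None:
                continue
            q = pool.get(key(ce, ce.supply_date + dt.timedelta(days=off)))
            while q:
                j = q[0]
                if used[j]:
                    q.popleft()
                    continue
                partner[i] = j
                used[j] = True
                q.popleft()
                break
    pairs = [
        (ce, pharmacy[j]) for ce, j in zip(claims, partner) if j is not None
    ]
    unmatched_claims = [ce for ce, j in zip(claims, partner) if j is None]
    unmatched_pharmacy = [pe for j, pe in enumerate(pharmacy) if not used[j]]
    if unmatched_pharmacy:
        logger.warning(
            "%d pharmacy events with no claims twin (e.g. private dispensing); "
            "kept for pharmacy-only coverage, excluded from the combined stream",
            len(unmatched_pharmacy),
        )
    return LinkageResult(pairs, unmatched_claims, unmatched_pharmacy)


def classify_pharmacy_use(result: LinkageResult) -> str:
    """``multiple`` iff at least one claims event lacks a pharmacy twin.

    A patient with no events at all is vacuously ``single`` (callers flag
    zero-event patients separately and exclude them from adherence
    analysis).
    """
    return result.pharmacy_use_class


def build_combined_stream(result: LinkageResult) -> list[DispensingEvent]:
    """One merged event per claims event.

    Matched events inherit the pharmacy event's dose instruction (and
    pharmacy id); unmatched claims events carry no instruction, so the
    downstream dose-resolution chain applies carry-forward or the standard
    dose. Pharmacy-only events are excluded (claims is the authoritative
    fill list).
    """
    combined = [
        with_instruction(ce, pe.dose_instruction, pe.pharmacy_id)
        for ce, pe in result.pairs
    ]
    combined += [with_instruction(ce, None) for ce in result.unmatched_claims]
    return sort_events(combined)


def linkage_audit(result: LinkageResult, patient_id: str = "") -> pd.DataFrame:
    """Per-event audit rows: match status and partner key."""
    rows = []
    for ce, pe in result.pairs:
        rows.append(
            {
                "patient_id": ce.patient_id,
                "product_code": ce.product_code,
                "supply_date": ce.supply_date.isoformat(),
                "status": "matched",
                "partner_date": pe.supply_date.isoformat(),
                "partner_pharmacy": pe.pharmacy_id or "",
            }
        )
    for ce in result.unmatched_claims:
        rows.append(
            {
                "patient_id": ce.patient_id,
                "product_code": ce.product_code,
                "supply_date": ce.supply_date.isoformat(),
                "status": "claims_only",
                "partner_date": "",
                "partner_pharmacy": "",
            }
        )
    for pe in result.unmatched_pharmacy:
        rows.append(
            {
                "patient_id": pe.patient_id,
                "product_code": pe.product_code,
                "supply_date": pe.supply_date.isoformat(),
                "status": "pharmacy_only",
                "partner_date": "",
                "partner_pharmacy": pe.pharmacy_id or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "product_code",
            "supply_date",
            "status",
            "partner_date",
            "partner_pharmacy",
        ],
    )
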