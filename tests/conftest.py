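"""Shared fixtures: a tiny catalog, event builders, and the day-grid
stock-consumption oracle used as the independent check on the interval
coverage engine."""

from __future__ import annotations

import datetime as dt
import math
from collections import defaultdict

import pytest

from pdclink.records import (
    Catalog,
    DispensingEvent,
    MedicationProduct,
    ObservationWindow,
)

DAY0 = dt.date(2018, 1, 1)


def day(n: int) -> dt.date:
    """Calendar date n days after the reference origin."""
    return DAY0 + dt.timedelta(days=int(n))


@pytest.fixture
def catalog() -> Catalog:
    return Catalog(
        [
            MedicationProduct("P001", "R03AK06", "combo inhaler 250", 120, 4.0, True),
            MedicationProduct("P002", "R03BA02", "ics inhaler 200", 200, 2.0, True),
            MedicationProduct("P003", "R03AK07", "combo inhaler 400", 60, 2.0, True),
            MedicationProduct("R001", "R03AC02", "reliever", 200, 4.0, False),
        ]
    )


@pytest.fixture
def window365() -> ObservationWindow:
    return ObservationWindow(DAY0, day(365))


def make_event(
    patient="p1",
    source="claims",
    on=0,
    product="P001",
    quantity=1,
    pharmacy_id=None,
    instruction=None,
) -> DispensingEvent:
    return DispensingEvent(
        patient_id=patient,
        source=source,
        supply_date=day(on) if isinstance(on, int) else on,
        product_code=product,
        quantity=quantity,
        pharmacy_id=pharmacy_id,
        dose_instruction=instruction,
    )


def day_grid_covered_days(fills, window: ObservationWindow) -> int:
    """Brute-force oracle: day-by-day stock consumption.

    ``fills`` is a list of (supply_date, product_code, days_of_supply)
    triples, where days_of_supply is the whole-day therapy content of the
    fill (floor(quantity x doses_per_pack / daily_dose), min 1 — the same
    per-fill flooring the interval method uses; sub-daily residue is not
    pooled across fills). Each simulated day first banks any same-day
    fills, then every product holding stock loses one day of stock; the day
    is covered if any product held stock. Fills outside the window are
    ignored; the grid ends at the window end.
    """
    by_date = defaultdict(list)
    for supply_date, product, days_of_supply in fills:
        if supply_date in window:
            by_date[supply_date].append((product, days_of_supply))
    stock: dict[str, int] = defaultdict(int)
    covered = 0
    d = window.start_date
    while d < window.end_date:
        for product, n in by_date.get(d, ()):
            stock[product] += n
        any_stock = False
        for product in list(stock):
            if stock[product] > 0:
                any_stock = True
                stock[product] -= 1
        if any_stock:
            covered += 1
        d += dt.timedelta(days=1)
    return covered


def day_grid_covered_days_doses(fills, window: ObservationWindow) -> int:
    """Dose-level oracle variant: stock is counted in dose units and each
    day consumes one daily dose per product. Coincides with the day-level
    oracle when every fill's dose content is an exact multiple of the daily
    dose.

    ``fills``: (supply_date, product_code, total_doses, daily_dose).
    """
    by_date = defaultdict(list)
    for supply_date, product, total, daily in fills:
        if supply_date in window:
            by_date[supply_date].append((product, total))
    daily_dose = {product: daily for _, product, _, daily in fills}
    stock: dict[str, float] = defaultdict(float)
    covered = 0
    d = window.start_date
    while d < window.end_date:
        for product, total in by_date.get(d, ()):
            stock[product] += total
        any_stock = False
        for product in list(stock):
            need = daily_dose[product]
            if stock[product] >= need:
                any_stock = True
                stock[product] -= need
        if any_stock:
            covered += 1
        d += dt.timedelta(days=1)
    return covered
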