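"""Coverage intervals, overlap adjustment, PDC, and the day-grid oracle
properties."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdclink.coverage as cov
from pdclink.dosing import PRESCRIBED, DoseRegimen, ResolvedEvent, resolve_doses
from pdclink.errors import ValidationError
from pdclink.records import ObservationWindow, sort_events

from conftest import (
    day,
    day_grid_covered_days,
    day_grid_covered_days_doses,
    make_event,
)


def resolved(ev, daily_dose):
    return ResolvedEvent(ev, DoseRegimen(daily_dose, daily_dose, 1.0, PRESCRIBED))


def _fixed_catalog():
    from pdclink.records import Catalog, MedicationProduct

    return Catalog(
        [
            MedicationProduct("P001", "R03AK06", "combo inhaler 250", 120, 4.0, True),
            MedicationProduct("P002", "R03BA02", "ics inhaler 200", 200, 2.0, True),
        ]
    )


CATALOG = _fixed_catalog()
WINDOW = ObservationWindow(day(0), day(365))


class TestDaysSupplied:
    @pytest.mark.parametrize(
        "quantity,pack,daily,expected",
        [
            (1, 120, 4.0, 30),
            (1, 120, 3.0, 40),  # the mean-of-range dose
            (2, 120, 4.0, 60),  # linear in quantity
            (1, 120, 3.5, 34),  # flooring
            (1, 1, 4.0, 1),  # minimum one day
        ],
    )
    def test_examples(self, quantity, pack, daily, expected):
        assert cov.days_supplied(quantity, pack, daily) == expected

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValidationError):
            cov.days_supplied(1, 120, 0.0)


class TestAdjustOverlaps:
    def test_early_refill_pushed_to_end_of_previous(self, catalog):
        events = [resolved(make_event(on=n), 4.0) for n in (0, 20)]
        iv = cov.adjust_overlaps(events, catalog)
        assert [(i.start, i.end_exclusive) for i in iv] == [
            (day(0), day(30)),
            (day(30), day(60)),
        ]

    def test_gap_preserved_when_no_overlap(self, catalog):
        events = [resolved(make_event(on=n), 4.0) for n in (0, 40)]
        iv = cov.adjust_overlaps(events, catalog)
        assert [(i.start, i.end_exclusive) for i in iv] == [
            (day(0), day(30)),
            (day(40), day(70)),
        ]

    def test_single_fill_identity(self, catalog):
        (iv,) = cov.adjust_overlaps([resolved(make_event(on=5), 4.0)], catalog)
        assert (iv.start, iv.end_exclusive) == (day(5), day(35))

    def test_no_supply_discarded_under_stacking(self, catalog):
        # three same-day fills: full stockpile carryover
        events = [resolved(make_event(on=0), 4.0)] * 3
        iv = cov.adjust_overlaps(events, catalog)
        assert iv[-1].end_exclusive == day(90)
        assert sum(i.n_days for i in iv) == 90

    def test_intervals_ordered_and_disjoint(self, catalog):
        events = [resolved(make_event(on=n), 4.0) for n in (0, 3, 6, 100, 102)]
        iv = cov.adjust_overlaps(events, catalog)
        for a, b in zip(iv, iv[1:]):
            assert a.end_exclusive <= b.start


class TestComputePdc:
    def test_no_events_zero(self, window365):
        assert cov.compute_pdc([], window365) == 0.0

    def test_full_coverage_100(self, window365):
        iv = cov.CoverageInterval("p1", "P001", day(0), day(365))
        assert cov.compute_pdc([iv], window365) == 100.0

    def test_two_fill_worked_example(self, catalog, window365):
        events = [resolved(make_event(on=n), 4.0) for n in (0, 20)]
        iv = cov.adjust_overlaps(events, catalog)
        pdc = cov.compute_pdc(iv, window365)
        assert pdc == pytest.approx(100 * 60 / 365)
        assert round(pdc, 2) == 16.44

    def test_union_not_sum_across_products(self, window365):
        ivs = [
            cov.CoverageInterval("p1", "P001", day(0), day(30)),
            cov.CoverageInterval("p1", "P002", day(0), day(30)),
        ]
        assert cov.covered_days(ivs, window365) == 30

    def test_coverage_truncated_at_window_end(self, catalog):
        window = ObservationWindow(day(0), day(30))
        events = [resolved(make_event(on=20), 4.0)]  # 30-day supply
        iv = cov.adjust_overlaps(events, catalog)
        assert cov.covered_days(iv, window) == 10

    def test_events_before_window_excluded(self, catalog):
        window = ObservationWindow(day(100), day(465))
        events = [make_event(on=95)]  # supply would reach into the window
        out = cov.run_regime(events, [], "claims_only", catalog, window)
        assert out.pdc == 0.0 and out.n_events == 0

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            ObservationWindow(day(0), day(0))


class TestRunRegime:
    def test_identical_streams_standard_doses_all_regimes_equal(
        self, catalog, window365
    ):
        claims = [make_event(on=n) for n in (0, 40, 80)]
        pharmacy = [
            make_event(source="pharmacy", on=n, pharmacy_id="PH1") for n in (0, 40, 80)
        ]
        pdcs = {
            r: cov.run_regime(claims, pharmacy, r, catalog, window365).pdc
            for r in cov.REGIMES
        }
        assert len(set(pdcs.values())) == 1

    def test_single_pharmacy_prescribed_dose_differs_from_claims(
        self, catalog, window365
    ):
        # prescribed 2 puffs bd on a product whose standard dose is 2/day:
        # pharmacy and combined agree, claims differs
        claims = [make_event(on=n, product="P002") for n in (0, 120)]
        pharmacy = [
            make_event(
                source="pharmacy", on=n, product="P002", pharmacy_id="PH1",
                instruction="2 puffs bd",
            )
            for n in (0, 120)
        ]
        ph = cov.run_regime(claims, pharmacy, "pharmacy_only", catalog, window365).pdc
        comb = cov.run_regime(claims, pharmacy, "combined", catalog, window365).pdc
        cl = cov.run_regime(claims, pharmacy, "claims_only", catalog, window365).pdc
        assert ph == comb
        assert ph != cl

    def test_multiple_pharmacy_user_pharmacy_below_combined(self, catalog, window365):
        # half the fills unobserved by the pharmacy
        claims = [make_event(on=n) for n in (0, 40, 80)]
        pharmacy = [make_event(source="pharmacy", on=0, pharmacy_id="PH1")]
        ph = cov.run_regime(claims, pharmacy, "pharmacy_only", catalog, window365).pdc
        comb = cov.run_regime(claims, pharmacy, "combined", catalog, window365).pdc
        assert ph < comb

    def test_unknown_regime_rejected(self, catalog, window365):
        with pytest.raises(ValidationError):
            cov.run_regime([], [], "mpr", catalog, window365)


class TestPatientAdherence:
    def test_threshold_boundary_inclusive(self):
        pa = cov.PatientAdherence("p1", 80.0, 79.99, 100.0, 80.0 >= 80, False, True,
                                  "single")
        assert pa.adherent_pharmacy and not pa.adherent_claims

    def test_out_of_range_pdc_rejected(self):
        with pytest.raises(ValidationError):
            cov.PatientAdherence("p1", 101.0, 50.0, 50.0, True, False, False, "single")

    def test_patient_adherence_classifies_and_thresholds(self, catalog, window365):
        claims = [make_event(on=n) for n in range(0, 360, 30)]
        pharmacy = [
            make_event(source="pharmacy", on=n, pharmacy_id="PH1")
            for n in range(0, 360, 60)
        ]
        pa = cov.patient_adherence("p1", claims, pharmacy, catalog, window365)
        assert pa.pharmacy_use_class == "multiple"
        assert pa.adherent_claims  # 12 monthly fills cover ~360/365
        assert pa.pdc_pharmacy < pa.pdc_combined == pa.pdc_claims


# ---------------------------------------------------------------------------
# oracle equivalence and order properties


def _random_patient(rng):
    """Random small fill set over <=2 products with assigned daily doses."""
    n_products = int(rng.integers(1, 3))
    products = ["P001", "P002"][:n_products]
    fills = []
    for code in products:
        daily = float(rng.choice([1.0, 2.0, 3.0, 3.5, 4.0, 7.0]))
        pack = int(rng.choice([30, 60, 120, 200]))
        for _ in range(int(rng.integers(1, 4))):
            fills.append(
                (
                    int(rng.integers(0, 330)),
                    code,
                    int(rng.integers(1, 3)),
                    pack,
                    daily,
                )
            )
    return fills


def _interval_covered(fills, window, catalog):
    from pdclink.records import Catalog, MedicationProduct

    # per-fill catalog lookup is only used for doses_per_pack; build events
    by_product = {}
    resolved_events = []
    for on, code, qty, pack, daily in fills:
        by_product.setdefault(code, pack)
        ev = make_event(on=on, product=code, quantity=qty)
        resolved_events.append(
            ResolvedEvent(ev, DoseRegimen(daily, daily, 1.0, PRESCRIBED))
        )
    cat = Catalog(
        [
            MedicationProduct(code, "R03", code, pack, 1.0, True)
            for code, pack in by_product.items()
        ]
    )
    intervals = cov.build_intervals(
        [r for r in resolved_events if r.event.supply_date in window], cat
    )
    return cov.covered_days(intervals, window)


def test_interval_method_equals_day_grid_oracle_randomized(window365):
    """Interval sweep with overlap adjustment == brute-force day-grid stock
    simulation, exactly, over randomized small patients."""
    rng = np.random.default_rng(20180801)
    for _ in range(300):
        fills = _random_patient(rng)
        grid = day_grid_covered_days(
            [
                (day(on), code, max(1, int(qty * pack // daily)))
                for on, code, qty, pack, daily in fills
            ],
            window365,
        )
        assert _interval_covered(fills, window365, None) == grid


def test_interval_method_equals_dose_level_oracle_on_divisible_instances(window365):
    """Where pack content divides evenly by the daily dose, the dose-level
    stock oracle agrees too."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        daily = float(rng.choice([1.0, 2.0, 4.0]))
        pack = int(rng.choice([120, 200])) if daily != 3 else 120
        fills = [
            (int(rng.integers(0, 300)), "P001", 1, pack, daily)
            for _ in range(int(rng.integers(1, 6)))
        ]
        doses_oracle = day_grid_covered_days_doses(
            [(day(on), code, qty * pk, dl) for on, code, qty, pk, dl in fills],
            window365,
        )
        assert _interval_covered(fills, window365, None) == doses_oracle


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    fills=st.lists(
        st.tuples(st.integers(0, 360), st.integers(1, 90)), min_size=1, max_size=6
    ),
    extra=st.tuples(st.integers(0, 360), st.integers(1, 90)),
)
def test_adding_an_event_never_decreases_coverage(fills, extra):
    def covered(fs):
        ivs = cov.build_intervals(
            [
                resolved(make_event(on=on), 120.0 / dur if dur else 120.0)
                for on, dur in fs
            ],
            CATALOG,
        )
        return cov.covered_days(ivs, WINDOW)

    assert covered(fills + [extra]) >= covered(fills)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    days=st.lists(st.integers(0, 360), min_size=1, max_size=6),
    lo=st.floats(0.5, 8.0),
    factor=st.floats(1.0, 4.0),
)
def test_increasing_daily_dose_never_increases_pdc(days, lo, factor):
    def pdc(daily):
        ivs = cov.build_intervals(
            [resolved(make_event(on=on), daily) for on in days], CATALOG
        )
        return cov.compute_pdc(ivs, WINDOW)

    assert pdc(lo * factor) <= pdc(lo) + 1e-12


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    fills=st.lists(
        st.tuples(st.integers(0, 364), st.integers(1, 100), st.integers(1, 400)),
        min_size=0,
        max_size=10,
    )
)
def test_pdc_bounded_under_adversarial_stockpiling(fills):
    """Huge quantities and dense refills can never push PDC above 100 or
    below 0."""
    ivs = cov.build_intervals(
        [
            resolved(make_event(on=on, quantity=qty), 480.0 / dur)
            for on, qty, dur in fills
        ],
        CATALOG,
    )
    pdc = cov.compute_pdc(ivs, WINDOW)
    assert 0.0 <= pdc <= 100.0
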