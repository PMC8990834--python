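"""Domain types and delimited-text IO for medication supply records.

Two record streams are modelled:

* **claims** — centrally collected administrative dispensing records
  (Pharmaceutical Benefits Scheme style): complete across pharmacies but
  without prescribed-dose instructions.
* **pharmacy** — a single pharmacy's local dispensing records, including
  free-text prescribed dose instructions, but blind to fills elsewhere.

A third source tag, ``combined``, marks events produced by merging the two
streams (claims dates/quantities with pharmacy dose instructions); it never
appears in input files.

All files are comma-delimited UTF-8 with a mandatory header row; dates are
ISO 8601 calendar dates (day granularity — adherence arithmetic never needs
time of day).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import MissingProductError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

SOURCE_CLAIMS = "claims"
SOURCE_PHARMACY = "pharmacy"
SOURCE_COMBINED = "combined"
SOURCES = (SOURCE_CLAIMS, SOURCE_PHARMACY, SOURCE_COMBINED)

CATALOG_COLUMNS = (
    "product_code",
    "atc_code",
    "name",
    "doses_per_pack",
    "standard_daily_dose",
    "is_controller",
)

EVENT_BASE_COLUMNS = ("patient_id", "supply_date", "product_code", "quantity")
EVENT_PHARMACY_COLUMNS = EVENT_BASE_COLUMNS + ("pharmacy_id", "dose_instruction")


@dataclass(frozen=True)
class MedicationProduct:
    """One catalog entry: a dispensed product and its standard daily dose.

    ``standard_daily_dose`` plays the role of the guideline minimum effective
    adult dose (dose units per day); ``doses_per_pack`` is the number of
    actuations or tablets in one dispensed unit.
    """

    product_code: str
    atc_code: str
    name: str
    doses_per_pack: int
    standard_daily_dose: float
    is_controller: bool

    def __post_init__(self) -> None:
        if not self.product_code:
            raise ValidationError("product_code must be non-empty")
        if int(self.doses_per_pack) < 1:
            raise ValidationError(
                f"product {self.product_code}: doses_per_pack must be >= 1, "
                f"got {self.doses_per_pack}"
            )
        if float(self.standard_daily_dose) <= 0:
            raise ValidationError(
                f"product {self.product_code}: standard_daily_dose must be > 0, "
                f"got {self.standard_daily_dose}"
            )


class Catalog:
    """Lookup of :class:`MedicationProduct` by product code."""

    def __init__(self, products: Iterable[MedicationProduct]):
        self._products: dict[str, MedicationProduct] = {}
        for p in products:
            if p.product_code in self._products:
                raise ValidationError(f"duplicate product_code {p.product_code!r}")
            self._products[p.product_code] = p

    def __getitem__(self, code: str) -> MedicationProduct:
        try:
            return self._products[code]
        except KeyError:
            raise MissingProductError(f"product_code {code!r} not in catalog") from None

    def __contains__(self, code: str) -> bool:
        return code in self._products

    def __len__(self) -> int:
        return len(self._products)

    def __iter__(self):
        return iter(self._products.values())

    def controllers(self) -> list[MedicationProduct]:
        return [p for p in self._products.values() if p.is_controller]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "product_code": p.product_code,
                "atc_code": p.atc_code,
                "name": p.name,
                "doses_per_pack": p.doses_per_pack,
                "standard_daily_dose": p.standard_daily_dose,
                "is_controller": p.is_controller,
            }
            for p in self._products.values()
        ]
        pd.DataFrame(rows, columns=list(CATALOG_COLUMNS)).to_csv(path, index=False)


def _parse_bool(value, where: str) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"{where}: cannot interpret {value!r} as boolean")


def load_catalog(path: str | Path) -> Catalog:
    """Read a medication catalog from CSV.

    Required columns: ``product_code, atc_code, name, doses_per_pack,
    standard_daily_dose, is_controller``. Duplicate product codes and
    non-positive doses/pack sizes are errors naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"catalog {path}: missing columns {sorted(missing)}")
    products = []
    for i, row in df.iterrows():
        where = f"catalog {path} row {i + 2}"  # +2: header + 1-based
        try:
            products.append(
                MedicationProduct(
                    product_code=str(row["product_code"]).strip(),
                    atc_code=str(row["atc_code"]).strip(),
                    name=str(row["name"]).strip(),
                    doses_per_pack=int(row["doses_per_pack"]),
                    standard_daily_dose=float(row["standard_daily_dose"]),
                    is_controller=_parse_bool(row["is_controller"], where),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{where}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    return Catalog(products)


def default_catalog() -> Catalog:
    """The bundled illustrative catalog of asthma inhaler products.

    Contains ~10 controller products (inhaled corticosteroids and ICS/LABA
    combinations) plus two reliever products. Standard daily doses play the
    role of guideline minimum effective adult doses but are illustrative
    values, not clinical guidance; replace the catalog for real analyses.
    """
    with resources.as_file(
        resources.files("pdclink").joinpath("data/default_catalog.csv")
    ) as p:
        return load_catalog(p)


@dataclass(frozen=True)
class DispensingEvent:
    """One medication supply act from either record stream.

    ``quantity`` counts dispensed packs. ``pharmacy_id`` and
    ``dose_instruction`` only occur on pharmacy-sourced (or merged) events;
    claims records never carry a prescribed dose.
    """

    patient_id: str
    source: str
    supply_date: dt.date
    product_code: str
    quantity: int
    pharmacy_id: Optional[str] = None
    dose_instruction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if int(self.quantity) < 1:
            raise ValidationError(
                f"event ({self.patient_id}, {self.supply_date}, "
                f"{self.product_code}): quantity must be >= 1"
            )
        if self.source == SOURCE_CLAIMS and self.dose_instruction is not None:
            raise ValidationError(
                "claims events cannot carry a dose instruction "
                f"({self.patient_id}, {self.supply_date}, {self.product_code})"
            )

    @property
    def sort_key(self):
        return (
            self.patient_id,
            self.product_code,
            self.supply_date.isoformat(),
            self.source,
            self.pharmacy_id or "",
            self.quantity,
        )


def sort_events(events: Iterable[DispensingEvent]) -> list[DispensingEvent]:
    """Stable total order by (patient, product, date, source, pharmacy, qty)."""
    return sorted(events, key=lambda e: e.sort_key)


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open date interval [start_date, end_date) counted in whole days."""

    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValidationError(
                f"window end {self.end_date} must be after start {self.start_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    def __contains__(self, day: dt.date) -> bool:
        return self.start_date <= day < self.end_date

    @classmethod
    def ending_at(cls, end_date: dt.date, days: int = 365) -> "ObservationWindow":
        """The `days`-long window immediately preceding `end_date`.

        Used to anchor the adherence window at a patient's enrolment date:
        the 12 months prior to enrolment, enrolment day excluded.
        """
        return cls(end_date - dt.timedelta(days=days), end_date)


@dataclass
class Patient:
    patient_id: str
    enrolment_date: dt.date
    demographics: dict = field(default_factory=dict)


def _parse_date(value, path, line_no: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise ValidationError(
            f"{path} line {line_no}: unparseable date {value!r} (expected ISO 8601)"
        ) from None


def read_events(
    path: str | Path,
    source: str,
    catalog: Optional[Catalog] = None,
    unknown_product: str = "warn",
) -> list[DispensingEvent]:
    """Read one event stream from CSV.

    ``source`` must be ``"claims"`` or ``"pharmacy"`` and fixes which optional
    columns are allowed: a claims file containing a ``dose_instruction``
    column is a schema error (claims data never includes the prescribed
    dose). If a catalog is supplied, events whose product code it lacks are
    dropped with a warning (``unknown_product="warn"``, default) or rejected
    (``"error"``).

    Returns events sorted by (patient_id, product_code, supply_date).
    """
    if source not in (SOURCE_CLAIMS, SOURCE_PHARMACY):
        raise ValidationError(f"source must be claims or pharmacy, got {source!r}")
    if unknown_product not in ("warn", "error"):
        raise ValidationError(f"unknown_product must be warn or error")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EVENT_BASE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if source == SOURCE_CLAIMS and "dose_instruction" in df.columns:
        raise SchemaError(
            f"{path}: claims files must not contain a dose_instruction column"
        )
    extra = set(df.columns) - set(EVENT_PHARMACY_COLUMNS)
    if extra:
        raise SchemaError(f"{path}: unexpected columns {sorted(extra)}")

    events: list[DispensingEvent] = []
    n_dropped = 0
    for i, row in df.iterrows():
        line_no = i + 2
        code = str(row["product_code"]).strip()
        if catalog is not None and code not in catalog:
            if unknown_product == "error":
                raise ValidationError(
                    f"{path} line {line_no}: unknown product_code {code!r}"
                )
            n_dropped += 1
            continue
        try:
            quantity = int(row["quantity"])
        except ValueError:
            raise ValidationError(
                f"{path} line {line_no}: quantity {row['quantity']!r} is not an integer"
            ) from None
        instruction = None
        if source == SOURCE_PHARMACY and "dose_instruction" in df.columns:
            raw = str(row["dose_instruction"]).strip()
            instruction = raw or None
        pharmacy_id = None
        if "pharmacy_id" in df.columns:
            raw = str(row["pharmacy_id"]).strip()
            pharmacy_id = raw or None
        try:
            events.append(
                DispensingEvent(
                    patient_id=str(row["patient_id"]).strip(),
                    source=source,
                    supply_date=_parse_date(row["supply_date"], path, line_no),
                    product_code=code,
                    quantity=quantity,
                    pharmacy_id=pharmacy_id,
                    dose_instruction=instruction,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
    if n_dropped:
        logger.warning(
            "%s: dropped %d events with product codes not in catalog", path, n_dropped
        )
    return sort_events(events)


def write_events(events: Sequence[DispensingEvent], path: str | Path) -> None:
    """Write an event stream to CSV (inverse of :func:`read_events`).

    Claims streams are written without the pharmacy-only columns so the file
    round-trips through the claims reader.
    """
    events = list(events)
    pharmacy_like = any(e.source != SOURCE_CLAIMS for e in events)
    rows = []
    for e in events:
        row = {
            "patient_id": e.patient_id,
            "supply_date": e.supply_date.isoformat(),
            "product_code": e.product_code,
            "quantity": e.quantity,
        }
        if pharmacy_like:
            row["pharmacy_id"] = e.pharmacy_id or ""
            row["dose_instruction"] = e.dose_instruction or ""
        rows.append(row)
    cols = list(EVENT_PHARMACY_COLUMNS if pharmacy_like else EVENT_BASE_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def filter_controllers(
    events: Iterable[DispensingEvent], catalog: Catalog
) -> list[DispensingEvent]:
    """Keep only events for controller (preventer) products.

    Adherence is defined over controller therapy; reliever dispensings are
    dropped and the count logged.
    """
    kept, dropped = [], 0
    for e in events:
        if catalog[e.product_code].is_controller:
            kept.append(e)
        else:
            dropped += 1
    if dropped:
        logger.info("filter_controllers: dropped %d non-controller events", dropped)
    return kept


def read_patients(path: str | Path) -> list[Patient]:
    """Read the patient table; columns beyond patient_id/enrolment_date become
    demographics."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"patient_id", "enrolment_date"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    demo_cols = [c for c in df.columns if c not in ("patient_id", "enrolment_date")]
    patients, seen = [], set()
    for i, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid in seen:
            raise ValidationError(f"{path} line {i + 2}: duplicate patient_id {pid!r}")
        seen.add(pid)
        patients.append(
            Patient(
                patient_id=pid,
                enrolment_date=_parse_date(row["enrolment_date"], path, i + 2),
                demographics={c: row[c] for c in demo_cols if str(row[c]).strip()},
            )
        )
    return patients


def write_patients(patients: Sequence[Patient], path: str | Path) -> None:
    demo_cols: list[str] = []
    for p in patients:
        for k in p.demographics:
            if k not in demo_cols:
                demo_cols.append(k)
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "enrolment_date": p.enrolment_date.isoformat(),
        }
        for c in demo_cols:
            row[c] = p.demographics.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["patient_id", "enrolment_date"] + demo_cols).to_csv(
        path, index=False
    )


def with_instruction(
    event: DispensingEvent, instruction: Optional[str], pharmacy_id: Optional[str] = None
) -> DispensingEvent:
    """Copy of `event` retagged as a merged (combined-source) event."""
    return replace(
        event,
        source=SOURCE_COMBINED,
        dose_instruction=instruction,
        pharmacy_id=pharmacy_id if pharmacy_id is not None else event.pharmacy_id,
    )
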