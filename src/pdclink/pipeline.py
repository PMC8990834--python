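"""End-to-end cohort adherence analysis.

Glues the stages together: read both event streams, filter to controller
products and each patient's 12-month pre-enrolment window, link the
streams, resolve doses, compute the PDC triple per patient, classify
pharmacy use, and emit the comparison tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import AnalysisConfig
from .coverage import ObservationWindow, patient_adherence, run_regime, REGIMES
from .records import Catalog, DispensingEvent, Patient, filter_controllers
from .stats import adherence_table, binary_adherence_analysis

logger = logging.getLogger(__name__)

ADHERENCE_COLUMNS = [
    "patient_id",
    "pdc_pharmacy",
    "pdc_claims",
    "pdc_combined",
    "adherent_pharmacy",
    "adherent_claims",
    "adherent_combined",
    "pharmacy_use_class",
]


@dataclass
class CohortResult:
    adherence: pd.DataFrame  # one row per analyzed patient
    excluded_zero_event: list[str] = field(default_factory=list)

    @property
    def n_analyzed(self) -> int:
        return len(self.adherence)


def _group_by_patient(events: Sequence[DispensingEvent]):
    by: dict[str, list[DispensingEvent]] = {}
    for e in events:
        by.setdefault(e.patient_id, []).append(e)
    return by


def compute_cohort_adherence(
    claims: Sequence[DispensingEvent],
    pharmacy: Sequence[DispensingEvent],
    patients: Sequence[Patient],
    catalog: Catalog,
    config: AnalysisConfig | None = None,
) -> CohortResult:
    """Per-patient PDC triple and pharmacy-use class for a whole cohort.

    Each patient's window is the ``window_days`` immediately preceding their
    enrolment date. Patients with zero controller events in both streams
    inside the window are excluded from the adherence table and reported
    separately (they have no adherence to estimate).
    """
    config = config or AnalysisConfig()
    claims_by = _group_by_patient(claims)
    pharmacy_by = _group_by_patient(pharmacy)
    rows, excluded = [], []
    for p in patients:
        window = ObservationWindow.ending_at(p.enrolment_date, config.window_days)
        c_events = claims_by.get(p.patient_id, [])
        ph_events = pharmacy_by.get(p.patient_id, [])
        n_controller = len(
            [e for e in filter_controllers(c_events, catalog)
             if e.supply_date in window]
        ) + len(
            [e for e in filter_controllers(ph_events, catalog)
             if e.supply_date in window]
        )
        if n_controller == 0:
            excluded.append(p.patient_id)
            continue
        pa = patient_adherence(
            p.patient_id,
            c_events,
            ph_events,
            catalog,
            window,
            threshold=config.adherence_threshold,
            date_tolerance_days=config.date_tolerance_days,
            match_quantity=config.match_quantity,
        )
        rows.append(
            {
                "patient_id": pa.patient_id,
                "pdc_pharmacy": pa.pdc_pharmacy,
                "pdc_claims": pa.pdc_claims,
                "pdc_combined": pa.pdc_combined,
                "adherent_pharmacy": pa.adherent_pharmacy,
                "adherent_claims": pa.adherent_claims,
                "adherent_combined": pa.adherent_combined,
                "pharmacy_use_class": pa.pharmacy_use_class,
            }
        )
    if excluded:
        logger.info(
            "excluded %d patients with no controller dispensing in window",
            len(excluded),
        )
    return CohortResult(
        adherence=pd.DataFrame(rows, columns=ADHERENCE_COLUMNS),
        excluded_zero_event=excluded,
    )


def regime_detail(
    claims: Sequence[DispensingEvent],
    pharmacy: Sequence[DispensingEvent],
    patients: Sequence[Patient],
    catalog: Catalog,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Long-form audit: one row per patient x regime with covered days,
    window length, events used and the truncation flag."""
    config = config or AnalysisConfig()
    claims_by = _group_by_patient(claims)
    pharmacy_by = _group_by_patient(pharmacy)
    rows = []
    for p in patients:
        window = ObservationWindow.ending_at(p.enrolment_date, config.window_days)
        for regime in REGIMES:
            out = run_regime(
                claims_by.get(p.patient_id, []),
                pharmacy_by.get(p.patient_id, []),
                regime,
                catalog,
                window,
                date_tolerance_days=config.date_tolerance_days,
                match_quantity=config.match_quantity,
            )
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "regime": regime,
                    "pdc": out.pdc,
                    "adherent": out.pdc >= config.adherence_threshold,
                    "covered_days": out.covered_days,
                    "window_days": out.window_days,
                    "events_used": out.n_events,
                    "truncated": out.truncated,
                }
            )
    return pd.DataFrame(rows)


def write_reports(
    result: CohortResult,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Write adherence.csv, adherence_table.csv and binary_adherence.csv."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["adherence"] = out_dir / "adherence.csv"
    result.adherence.to_csv(paths["adherence"], index=False)
    if len(result.adherence) >= 2:
        paths["table"] = out_dir / "adherence_table.csv"
        adherence_table(
            result.adherence, wrs=config.paired_wrs, equal_var=config.equal_var
        ).to_csv(paths["table"], index=False)
        paths["binary"] = out_dir / "binary_adherence.csv"
        binary_adherence_analysis(
            result.adherence, threshold=config.adherence_threshold
        ).to_csv(paths["binary"], index=False)
    if result.excluded_zero_event:
        paths["excluded"] = out_dir / "excluded_patients.csv"
        pd.DataFrame({"patient_id": result.excluded_zero_event}).to_csv(
            paths["excluded"], index=False
        )
    return paths
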