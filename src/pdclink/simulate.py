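"""Synthetic paired claims/pharmacy cohorts with known ground truth.

Real linked claims + pharmacy dispensing datasets cannot be redistributed,
so every pipeline stage here is exercised against a generator that emulates
the statistical structure of such a study:

* each patient has a latent refill propensity θ ~ Beta(α, β); refill gaps
  beyond supply exhaustion are geometric, scaled by (1 − θ), so adherent
  patients refill on time and poor adherers leave long gaps;
* every fill enters the claims stream (claims are complete by definition);
* a configurable fraction of patients are *multiple-pharmacy users*: each
  of their fills is unobserved by the study pharmacy with some probability
  (at least one fill is forced unobserved so the class is identifiable by
  exact record matching). If the unobserved-fill probability is zero the
  whole cohort is generated — and labelled — single-pharmacy;
* each product's true daily dose is the standard dose times a multiplier
  drawn from {0.5, 1, 2}; dose instructions encoding the true dose (point
  or range form) are attached to pharmacy events, omitted at random with a
  configurable probability;
* optional date jitter on pharmacy events emulates messy exports and
  degrades exact-date linkage.

The ground truth records each patient's true class, true daily doses, true
covered-day set, and the PDC a regime would yield on the complete
(pre-split) event stream — which is what recovery tests compare against.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import build_intervals, covered_days
from .dosing import PRESCRIBED, DoseRegimen, ResolvedEvent
from .errors import ValidationError
from .linkage import MULTIPLE, SINGLE
from .records import (
    SOURCE_CLAIMS,
    SOURCE_PHARMACY,
    Catalog,
    DispensingEvent,
    ObservationWindow,
    Patient,
    default_catalog,
    sort_events,
    write_events,
    write_patients,
)

_STUDY_START = dt.date(2018, 8, 1)  # enrolment span of the emulated study
_ENROLMENT_SPAN_DAYS = 212  # through March of the following year


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the generator.

    Defaults emulate the emulated study's structure: 289 analyzed patients,
    a 365-day window, 33% multiple-pharmacy users, each of whose fills is
    collected at a non-study pharmacy with probability 0.5. Beta(2, 2)
    refill propensity with a 45-day geometric gap scale spreads mean PDC
    over roughly the 40–65% band. Dose multipliers slightly favour m ≥ 1,
    matching the observed direction that a standard-dose assumption
    overestimates coverage.
    """

    n_patients: int = 289
    window_days: int = 365
    fraction_multiple_pharmacy: float = 0.33
    unobserved_fill_probability: float = 0.5
    adherence_alpha: float = 2.0
    adherence_beta: float = 2.0
    refill_gap_mean_days: float = 45.0
    dose_multiplier_probs: dict = field(
        default_factory=lambda: {0.5: 0.15, 1.0: 0.55, 2.0: 0.30}
    )
    dose_range_probability: float = 0.2
    instruction_missing_probability: float = 0.1
    two_product_probability: float = 0.4
    quantity_two_probability: float = 0.1
    date_jitter_days: int = 0
    adherence_class_correlation: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.window_days < 30:
            raise ValidationError("window_days must be >= 30")
        for name in (
            "fraction_multiple_pharmacy",
            "unobserved_fill_probability",
            "dose_range_probability",
            "instruction_missing_probability",
            "two_product_probability",
            "quantity_two_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.adherence_alpha <= 0 or self.adherence_beta <= 0:
            raise ValidationError("Beta shape parameters must be positive")
        if self.refill_gap_mean_days < 1:
            raise ValidationError("refill_gap_mean_days must be >= 1")
        if not -1.0 <= self.adherence_class_correlation <= 1.0:
            raise ValidationError("adherence_class_correlation must be in [-1, 1]")
        total = sum(self.dose_multiplier_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError("dose_multiplier_probs must sum to 1")
        if any(m <= 0 for m in self.dose_multiplier_probs):
            raise ValidationError("dose multipliers must be positive")
        if self.date_jitter_days < 0:
            raise ValidationError("date_jitter_days must be >= 0")


_FREQ_WORDS = {
    1: ("once daily", "mane", "nocte", "every morning", "every night"),
    2: ("twice daily", "bd"),
    3: ("three times daily", "tds"),
    4: ("four times daily", "qid"),
}
_UNIT_WORDS = ("puff", "inhalation")


def _instruction_text(daily_dose: int, rng: np.random.Generator,
                      want_range: bool) -> str:
    """A grammar-conformant instruction whose parsed daily dose equals
    `daily_dose` (integer dose units/day)."""
    assert daily_dose >= 1
    if want_range:
        # need per-admin mean q = d/f with q >= 1.5 and 2q integral
        candidates = [f for f in (1, 2, 3, 4)
                      if (2 * daily_dose) % f == 0 and daily_dose / f >= 1.5]
        if candidates:
            f = int(rng.choice(candidates))
            q = daily_dose / f
            if q == int(q):
                lo, hi = int(q) - 1, int(q) + 1
            else:
                lo, hi = int(q - 0.5), int(q + 0.5)
            unit = str(rng.choice(_UNIT_WORDS)) + "s"
            freq = str(rng.choice(_FREQ_WORDS[f]))
            return f"{lo}-{hi} {unit} {freq}"
        # fall through to point form (e.g. daily dose 1)
    divisors = [f for f in (1, 2, 3, 4) if daily_dose % f == 0]
    f = int(rng.choice(divisors))
    q = daily_dose // f
    unit = str(rng.choice(_UNIT_WORDS)) + ("" if q == 1 else "s")
    freq = str(rng.choice(_FREQ_WORDS[f]))
    return f"{q} {unit} {freq}"


@dataclass
class CohortData:
    """A generated cohort: both event streams, patient table, catalog,
    per-patient ground truth (DataFrame) and the true covered-day sets
    (in-memory only; too large to serialize usefully)."""

    claims: list[DispensingEvent]
    pharmacy: list[DispensingEvent]
    patients: list[Patient]
    truth: pd.DataFrame
    catalog: Catalog
    config: SyntheticCohortConfig
    covered_day_sets: dict[str, set] = field(default_factory=dict)

    def write_dir(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "claims": out_dir / "claims.csv",
            "pharmacy": out_dir / "pharmacy.csv",
            "patients": out_dir / "patients.csv",
            "truth": out_dir / "truth.csv",
            "catalog": out_dir / "catalog.csv",
        }
        write_events(self.claims, paths["claims"])
        write_events(self.pharmacy, paths["pharmacy"])
        write_patients(self.patients, paths["patients"])
        self.truth.to_csv(paths["truth"], index=False)
        self.catalog.to_csv(paths["catalog"])
        return paths


def _true_pdc(fills: Sequence[tuple[DispensingEvent, float]],
              catalog: Catalog, window: ObservationWindow) -> tuple[float, int, list]:
    """PDC on the complete fill list at the given per-fill daily doses."""
    resolved = [
        ResolvedEvent(ev, DoseRegimen(d, d, 1.0, PRESCRIBED)) for ev, d in fills
    ]
    intervals = build_intervals(resolved, catalog)
    covered = covered_days(intervals, window)
    return 100.0 * covered / window.n_days, covered, intervals


def _covered_day_set(intervals, window) -> set:
    days = set()
    for iv in intervals:
        d = max(iv.start, window.start_date)
        end = min(iv.end_exclusive, window.end_date)
        while d < end:
            days.add(d)
            d += dt.timedelta(days=1)
    return days


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
    seed: Optional[int] = None,
    catalog: Optional[Catalog] = None,
) -> CohortData:
    """Draw a full synthetic cohort; byte-identical for a fixed seed/config.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SyntheticCohortConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    controllers = catalog.controllers()
    multipliers = sorted(config.dose_multiplier_probs)
    mult_probs = [config.dose_multiplier_probs[m] for m in multipliers]

    claims: list[DispensingEvent] = []
    pharmacy: list[DispensingEvent] = []
    patients: list[Patient] = []
    truth_rows = []
    covered_sets: dict[str, set] = {}

    for i in range(config.n_patients):
        pid = f"S{i + 1:04d}"
        study_pharmacy = f"PH{(i % 95) + 1:03d}"
        enrolment = _STUDY_START + dt.timedelta(
            days=int(rng.integers(0, _ENROLMENT_SPAN_DAYS))
        )
        window = ObservationWindow.ending_at(enrolment, config.window_days)

        theta = float(rng.beta(config.adherence_alpha, config.adherence_beta))
        # class assignment, optionally correlated with refill propensity
        rho = config.adherence_class_correlation
        if config.unobserved_fill_probability == 0.0:
            # no routing noise: multiple use would be unidentifiable, so the
            # whole cohort is single-pharmacy by construction
            is_multiple = False
        elif rho != 0.0 and rng.random() < abs(rho):
            q = float(
                sps.beta.cdf(theta, config.adherence_alpha, config.adherence_beta)
            )
            # rho > 0: the most adherent patients are the multiple users
            is_multiple = (
                q > 1.0 - config.fraction_multiple_pharmacy
                if rho > 0
                else q < config.fraction_multiple_pharmacy
            )
        else:
            is_multiple = rng.random() < config.fraction_multiple_pharmacy

        n_products = 2 if rng.random() < config.two_product_probability else 1
        products = list(
            rng.choice(len(controllers), size=n_products, replace=False)
        )
        fills: list[tuple[DispensingEvent, float]] = []  # (claims event, true dose)
        instr_by_fill: list[Optional[str]] = []
        prod_multipliers: list[float] = []
        prod_codes: list[str] = []
        true_doses: list[float] = []
        for pidx in products:
            product = controllers[int(pidx)]
            m = float(rng.choice(multipliers, p=mult_probs))
            if m * product.standard_daily_dose < 1.0:
                m = 1.0  # a sub-unit daily dose is not expressible as an instruction
            true_daily = m * product.standard_daily_dose
            assert true_daily == int(true_daily)
            want_range = rng.random() < config.dose_range_probability
            text = _instruction_text(int(true_daily), rng, want_range)
            prod_multipliers.append(m)
            prod_codes.append(product.product_code)
            true_doses.append(true_daily)

            t = window.start_date + dt.timedelta(days=int(rng.integers(0, 30)))
            n_safety = 0
            while t < window.end_date and n_safety < 80:
                n_safety += 1
                quantity = 2 if rng.random() < config.quantity_two_probability else 1
                ev = DispensingEvent(
                    patient_id=pid,
                    source=SOURCE_CLAIMS,
                    supply_date=t,
                    product_code=product.product_code,
                    quantity=quantity,
                )
                fills.append((ev, true_daily))
                missing = rng.random() < config.instruction_missing_probability
                instr_by_fill.append(None if missing else text)
                duration = max(
                    1, math.floor(quantity * product.doses_per_pack / true_daily)
                )
                gap = int(
                    math.floor(
                        (1.0 - theta)
                        * rng.geometric(1.0 / config.refill_gap_mean_days)
                    )
                )
                t = t + dt.timedelta(days=duration + gap)

        # routing: which fills the study pharmacy observed
        n_fills = len(fills)
        if is_multiple:
            unobserved = rng.random(n_fills) < config.unobserved_fill_probability
            if not unobserved.any():
                unobserved[int(rng.integers(0, n_fills))] = True
        else:
            unobserved = np.zeros(n_fills, dtype=bool)

        for (ev, _), instr, miss in zip(fills, instr_by_fill, unobserved):
            claims.append(ev)
            if not miss:
                date = ev.supply_date
                if config.date_jitter_days:
                    date = date + dt.timedelta(
                        days=int(
                            rng.integers(
                                -config.date_jitter_days,
                                config.date_jitter_days + 1,
                            )
                        )
                    )
                pharmacy.append(
                    replace(
                        ev,
                        source=SOURCE_PHARMACY,
                        supply_date=date,
                        pharmacy_id=study_pharmacy,
                        dose_instruction=instr,
                    )
                )

        true_pdc, true_covered, intervals = _true_pdc(fills, catalog, window)
        true_pdc_claims, _, _ = _true_pdc(
            [(ev, catalog[ev.product_code].standard_daily_dose) for ev, _ in fills],
            catalog,
            window,
        )
        covered_sets[pid] = _covered_day_set(intervals, window)
        patients.append(Patient(patient_id=pid, enrolment_date=enrolment))
        truth_rows.append(
            {
                "patient_id": pid,
                "true_class": MULTIPLE if is_multiple else SINGLE,
                "theta": theta,
                "products": ";".join(prod_codes),
                "true_daily_doses": ";".join(f"{d:g}" for d in true_doses),
                "dose_multipliers": ";".join(f"{m:g}" for m in prod_multipliers),
                "multiplier_min": min(prod_multipliers),
                "multiplier_max": max(prod_multipliers),
                "n_fills": n_fills,
                "n_unobserved": int(unobserved.sum()),
                "true_covered_days": true_covered,
                "true_pdc": true_pdc,
                "true_pdc_claims": true_pdc_claims,
            }
        )

    return CohortData(
        claims=sort_events(claims),
        pharmacy=sort_events(pharmacy),
        patients=patients,
        truth=pd.DataFrame(truth_rows),
        catalog=catalog,
        config=config,
        covered_day_sets=covered_sets,
    )


def recovery_report(cohort: CohortData, adherence: pd.DataFrame) -> dict:
    """Compare pipeline estimates against generator ground truth.

    Returns a dict with:

    * ``classification_accuracy`` — fraction of patients whose
      single/multiple call matches the true routing class;
    * ``claims_pdc_exact_rate`` — fraction whose claims-regime PDC equals
      the truth's claims-regime PDC exactly;
    * ``pharmacy_bias_multiple`` — mean (pharmacy-only PDC − true PDC)
      among true multiple users; expected negative, since the study
      pharmacy misses part of their fills;
    * dose-multiplier sign law over patients whose products share one
      multiplier m: m > 1 ⇒ combined ≤ claims, m = 1 ⇒ equal, m < 1 ⇒
      combined ≥ claims (monotone law; strict inequality additionally
      counted — equality at m ≠ 1 occurs only when coverage saturates the
      window tail).
    """
    df = cohort.truth.merge(adherence, on="patient_id", how="inner")
    eps = 1e-9
    out: dict = {"n_patients": int(len(df))}
    out["classification_accuracy"] = float(
        (df["pharmacy_use_class"] == df["true_class"]).mean()
    )
    out["claims_pdc_exact_rate"] = float(
        (np.isclose(df["pdc_claims"], df["true_pdc_claims"], rtol=0, atol=eps)).mean()
    )
    mult = df[df["true_class"] == MULTIPLE]
    out["pharmacy_bias_multiple"] = (
        float((mult["pdc_pharmacy"] - mult["true_pdc"]).mean())
        if len(mult)
        else math.nan
    )
    uniform = df[df["multiplier_min"] == df["multiplier_max"]]
    diffs = uniform["pdc_combined"] - uniform["pdc_claims"]
    m = uniform["multiplier_min"]
    consistent = np.where(
        m > 1, diffs <= eps, np.where(m < 1, diffs >= -eps, np.abs(diffs) <= eps)
    )
    strict = (m != 1) & (np.abs(diffs) > eps)
    out["sign_law_n"] = int(len(uniform))
    out["sign_law_consistent"] = int(consistent.sum())
    out["sign_law_strict"] = int(strict.sum())
    out["sign_law_all_consistent"] = bool(consistent.all()) if len(uniform) else True
    return out
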