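"""Analysis configuration, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    """Knobs for a cohort adherence run.

    window_days
        Length of the observation window anchored immediately before each
        patient's enrolment date (days). Default 365: a 12-month history.
    adherence_threshold
        PDC percent at or above which a patient counts as adherent
        (inclusive). Default 80.
    unknown_product
        ``warn`` drops events with product codes absent from the catalog
        (logged); ``error`` rejects the file.
    date_tolerance_days / match_quantity
        Record-linkage keys: claims and pharmacy events pair on
        (product, date[, quantity]) with optional +/- day slack.
    paired_wrs
        Rank companion for paired comparisons: ``signed_rank`` (default) or
        ``rank_sum`` applied to the differences.
    equal_var
        Use the pooled-variance Student t instead of Welch for unpaired
        comparisons.
    """

    window_days: int = 365
    adherence_threshold: float = 80.0
    unknown_product: str = "warn"
    date_tolerance_days: int = 0
    match_quantity: bool = True
    paired_wrs: str = "signed_rank"
    equal_var: bool = False

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        if self.unknown_product not in ("warn", "error"):
            raise ValidationError("unknown_product must be warn or error")
        if self.date_tolerance_days < 0:
            raise ValidationError("date_tolerance_days must be >= 0")
        if self.paired_wrs not in ("signed_rank", "rank_sum"):
            raise ValidationError("paired_wrs must be signed_rank or rank_sum")
        if not 0 < self.adherence_threshold <= 100:
            raise ValidationError("adherence_threshold must be in (0, 100]")


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = AnalysisConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
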