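"""Rejection criteria registry and sensory-anchored shelf-life integration.

Each assay carries a rejection criterion (the value at which the fish is no
longer acceptable) and hence an estimated rejection day.  The integrated
shelf life is anchored on the sensory (QIM) rejection day — sensory
analysis is the reference method the instrumental assays corroborate — and
is reported at half-day resolution with an uncertainty taken from the QI
calibration's day-scale estimation error, floored at half a day to match
the daily sampling grid.  The remaining assays act as a consistency check:
the estimate is flagged consistent when every corroborating assay's
rejection interval midpoint falls within +/-1.5 days of it.

Default criteria (overridable from a YAML/JSON file):

=============  =========  ======================
assay          direction  threshold
=============  =========  ======================
qim            >=         17.5 (QI, off-odors)
torrymeter     <=         8 (instrument units)
tvc_nt/tvc_ir  >=         8.0 log10 cfu/cm2
h2s            >=         7.5 log10 cfu/cm2
tma            >=         12.5 mg/100 g (regulatory limit 12)
=============  =========  ======================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import LinearCalibration
from .kinetics import CrossingEstimate

__all__ = [
    "CriterionSpec",
    "RejectionCriteria",
    "ShelfLifeEstimate",
    "default_criteria",
    "load_criteria",
    "sensory_rejection_day",
    "integrate_shelf_life",
    "round_half_day",
]

#: Regulatory limit for TMA under Directive 91/493/EEC, mg/100 g.
TMA_REGULATORY_LIMIT = 12.0

#: Corroborating assays must sit within this many days of the sensory anchor.
CONSISTENCY_TOLERANCE_DAYS = 1.5

MIN_UNCERTAINTY_DAYS = 0.5


@dataclass(frozen=True)
class CriterionSpec:
    assay: str
    threshold: float
    direction: str  # ">=" for rising indicators, "<=" for falling
    units: str
    note: str = ""


@dataclass(frozen=True)
class RejectionCriteria:
    """Per-assay rejection criteria; mapping-like access by assay name."""

    criteria: dict[str, CriterionSpec] = field(default_factory=dict)

    def __getitem__(self, assay: str) -> CriterionSpec:
        return self.criteria[assay]

    def __contains__(self, assay: str) -> bool:
        return assay in self.criteria

    def threshold(self, assay: str) -> float:
        return self.criteria[assay].threshold


@dataclass(frozen=True)
class ShelfLifeEstimate:
    sensory: CrossingEstimate
    others: tuple[CrossingEstimate, ...]
    integrated_days: float
    uncertainty_days: float
    consistent: bool


_DEFAULTS = (
    CriterionSpec("qim", 17.5, ">=", "QI demerit points", "off-odors present"),
    CriterionSpec("torrymeter", 8.0, "<=", "instrument units", "slope-change value"),
    CriterionSpec("tvc_nt", 8.0, ">=", "log10 cfu/cm2", "acceptable band 7-9"),
    CriterionSpec("tvc_ir", 8.0, ">=", "log10 cfu/cm2", "acceptable band 7-9"),
    CriterionSpec("h2s", 7.5, ">=", "log10 cfu/cm2", "acceptable band 7-9"),
    CriterionSpec(
        "tma", 12.5, ">=", "mg/100 g", f"regulatory limit {TMA_REGULATORY_LIMIT:g} mg/100 g"
    ),
)


def default_criteria() -> RejectionCriteria:
    """The built-in rejection-criteria registry for ice-stored amberjack."""
    return RejectionCriteria(criteria={c.assay: c for c in _DEFAULTS})


def load_criteria(path: str | Path) -> RejectionCriteria:
    """Defaults overridden by a YAML/JSON mapping assay -> threshold (or spec)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    base = {c.assay: c for c in _DEFAULTS}
    for assay, override in (doc or {}).items():
        if isinstance(override, dict):
            old = base.get(assay)
            base[assay] = CriterionSpec(
                assay=assay,
                threshold=float(override["threshold"]),
                direction=str(override.get("direction", old.direction if old else ">=")),
                units=str(override.get("units", old.units if old else "")),
                note=str(override.get("note", "")),
            )
        else:
            if assay not in base:
                raise ValueError(
                    f"override for unknown assay {assay!r} must be a full mapping"
                )
            old = base[assay]
            base[assay] = CriterionSpec(
                assay=assay,
                threshold=float(override),
                direction=old.direction,
                units=old.units,
                note=old.note,
            )
    for spec in base.values():
        if not math.isfinite(spec.threshold):
            raise ValueError(f"criterion for {spec.assay!r} is not finite")
        if spec.direction not in (">=", "<="):
            raise ValueError(f"criterion direction must be >= or <=, got {spec.direction!r}")
    return RejectionCriteria(criteria=base)


def round_half_day(x: float) -> float:
    """Round to the nearest half day (half-up, so 11.75 -> 12.0)."""
    return math.floor(2.0 * x + 0.5) / 2.0


def sensory_rejection_day(
    cal: LinearCalibration,
    criteria: RejectionCriteria | None = None,
    max_qi: float | None = None,
) -> CrossingEstimate:
    """Day the fitted QI line reaches the sensory rejection threshold."""
    criteria = criteria or default_criteria()
    threshold = criteria.threshold("qim")
    if cal.slope <= 0:
        raise ValueError("QI calibration slope must be positive for a rejection day")
    if max_qi is not None and threshold > max_qi:
        return CrossingEstimate("qim", threshold, float("nan"), None, "beyond_window")
    day = (threshold - cal.intercept) / cal.slope
    day = max(day, 0.0)
    lo = math.floor(day)
    return CrossingEstimate("qim", threshold, float(day), (lo, lo + 1), "crossed")


def integrate_shelf_life(
    sensory: CrossingEstimate,
    others: list[CrossingEstimate],
    cal: LinearCalibration,
) -> ShelfLifeEstimate:
    """Combine per-assay rejection days into one shelf-life estimate.

    integrated = sensory rejection day, half-day rounded;
    uncertainty = calibration RMSE (days) half-day rounded, floored at 0.5;
    consistent  = every corroborating assay with a crossed interval has its
    interval midpoint within +/-1.5 days of the integrated value.
    """
    if sensory is None or sensory.status != "crossed":
        raise ValueError("sensory rejection day is the anchor and must be available")
    integrated = round_half_day(sensory.crossing_day)
    rmse = cal.rmse_days if math.isfinite(cal.rmse_days) else 0.0
    uncertainty = max(round_half_day(rmse), MIN_UNCERTAINTY_DAYS)
    consistent = True
    for est in others:
        if est.status != "crossed" or est.interval is None:
            consistent = False
            continue
        mid = 0.5 * (est.interval[0] + est.interval[1])
        if abs(mid - integrated) > CONSISTENCY_TOLERANCE_DAYS:
            consistent = False
    return ShelfLifeEstimate(
        sensory=sensory,
        others=tuple(others),
        integrated_days=float(integrated),
        uncertainty_days=float(uncertainty),
        consistent=bool(consistent),
    )
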