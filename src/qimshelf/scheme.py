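"""QIM scheme data model, validation and demerit-point scoring.

The Quality Index Method (QIM) grades seafood freshness by assigning
integer demerit points (0 = totally fresh) to a fixed set of sensory
parameters grouped under quality attributes (appearance, texture, eyes,
gills).  The per-fish Quality Index (QI) is the plain sum of the demerit
points, so a scheme's ceiling is the sum of per-parameter maxima.

Parameters whose degradation never shows a fourth distinguishable stage
carry a maximum below 3 (e.g. anus, eye shape); the model therefore stores
each parameter's own score range instead of assuming 0-3 everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Descriptor",
    "Parameter",
    "AttributeGroup",
    "QIMScheme",
    "SensoryObservation",
    "QIRecord",
    "SchemeError",
    "ObservationError",
    "load_scheme",
    "write_scheme",
    "default_scheme",
    "max_qi",
    "compute_qi",
    "validate_observation",
    "read_observations",
    "write_observations",
    "score_observations",
]

DEFAULT_SCHEME_RESOURCE = "seriola_dumerili.yaml"

#: Hard ceiling on any single demerit score in a QIM scheme.
MAX_SCORE = 3


class SchemeError(ValueError):
    """A scheme file failed validation (structure or scoring invariants)."""


class ObservationError(ValueError):
    """An observation is inconsistent with the scheme it is scored against."""


@dataclass(frozen=True)
class Descriptor:
    """One scored degradation stage of a sensory parameter."""

    score: int
    text: str


@dataclass(frozen=True)
class Parameter:
    """A scored sensory parameter (e.g. gill odor) with ordered descriptors."""

    name: str
    descriptors: tuple[Descriptor, ...]

    @property
    def max_score(self) -> int:
        return self.descriptors[-1].score

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(d.score for d in self.descriptors)


@dataclass(frozen=True)
class AttributeGroup:
    """A quality attribute (e.g. Gills) holding one or more parameters."""

    label: str
    parameters: tuple[Parameter, ...]


@dataclass(frozen=True)
class QIMScheme:
    """An ordered demerit-point scheme for one species/product."""

    name: str
    groups: tuple[AttributeGroup, ...]

    @property
    def parameters(self) -> tuple[Parameter, ...]:
        return tuple(p for g in self.groups for p in g.parameters)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"scheme has no parameter named {name!r}")


@dataclass(frozen=True)
class SensoryObservation:
    """One fish x assessor x day vector of demerit scores."""

    fish_id: str
    assessor_id: str
    day: float
    scores: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class QIRecord:
    """A summed quality index for one observation."""

    fish_id: str
    assessor_id: str
    day: float
    qi: float


def _validate_scheme(scheme: QIMScheme) -> None:
    seen: set[str] = set()
    for group in scheme.groups:
        if not group.parameters:
            raise SchemeError(f"attribute group {group.label!r} has no parameters")
        for param in group.parameters:
            if param.name in seen:
                raise SchemeError(f"duplicate parameter name {param.name!r}")
            seen.add(param.name)
            scores = param.scores
            if not scores:
                raise SchemeError(f"parameter {param.name!r} has no descriptors")
            if list(scores) != list(range(len(scores))):
                raise SchemeError(
                    f"parameter {param.name!r} scores must be consecutive "
                    f"integers starting at 0, got {scores}"
                )
            if param.max_score > MAX_SCORE:
                raise SchemeError(
                    f"parameter {param.name!r} maximum score {param.max_score} "
                    f"exceeds the demerit-point ceiling {MAX_SCORE}"
                )


def _scheme_from_mapping(doc: Mapping) -> QIMScheme:
    try:
        groups = tuple(
            AttributeGroup(
                label=str(g["label"]),
                parameters=tuple(
                    Parameter(
                        name=str(p["name"]),
                        descriptors=tuple(
                            Descriptor(score=int(d["score"]), text=str(d["text"]))
                            for d in p["descriptors"]
                        ),
                    )
                    for p in g["parameters"]
                ),
            )
            for g in doc["groups"]
        )
        scheme = QIMScheme(name=str(doc["name"]), groups=groups)
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"malformed scheme document: {exc}") from exc
    _validate_scheme(scheme)
    return scheme


def load_scheme(path: str | Path) -> QIMScheme:
    """Load and validate a QIM scheme from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemeError(f"could not parse scheme file {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise SchemeError(f"scheme file {path} does not contain a mapping")
    return _scheme_from_mapping(doc)


def default_scheme() -> QIMScheme:
    """The packaged 25-demerit-point greater amberjack scheme."""
    ref = resources.files("qimshelf.data").joinpath(DEFAULT_SCHEME_RESOURCE)
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _scheme_from_mapping(doc)


def _scheme_to_mapping(scheme: QIMScheme) -> dict:
    return {
        "name": scheme.name,
        "groups": [
            {
                "label": g.label,
                "parameters": [
                    {
                        "name": p.name,
                        "descriptors": [
                            {"score": d.score, "text": d.text} for d in p.descriptors
                        ],
                    }
                    for p in g.parameters
                ],
            }
            for g in scheme.groups
        ],
    }


def write_scheme(scheme: QIMScheme, path: str | Path) -> None:
    """Serialize a scheme back to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    doc = _scheme_to_mapping(scheme)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def max_qi(scheme: QIMScheme) -> int:
    """Scheme ceiling: sum of per-parameter maximum demerit scores."""
    return sum(p.max_score for p in scheme.parameters)


def validate_observation(
    obs: SensoryObservation, scheme: QIMScheme
) -> list[str]:
    """Return human-readable violations; empty list means valid.

    Violations are data, not exceptions: panels produce occasional slips and
    the caller decides whether to reject the sheet or a single row.
    """
    violations: list[str] = []
    names = set(scheme.parameter_names)
    for name in scheme.parameter_names:
        if name not in obs.scores:
            violations.append(
                f"fish {obs.fish_id}, assessor {obs.assessor_id}: "
                f"missing score for parameter {name!r}"
            )
    for name, score in obs.scores.items():
        if name not in names:
            violations.append(
                f"fish {obs.fish_id}, assessor {obs.assessor_id}: "
                f"unknown parameter {name!r}"
            )
            continue
        param = scheme.parameter(name)
        if not float(score).is_integer():
            violations.append(
                f"fish {obs.fish_id}, assessor {obs.assessor_id}: "
                f"parameter {name!r} score {score} is not an integer"
            )
        elif not 0 <= int(score) <= param.max_score:
            violations.append(
                f"fish {obs.fish_id}, assessor {obs.assessor_id}: "
                f"parameter {name!r} score {score} outside 0..{param.max_score}"
            )
    if obs.day < 0:
        violations.append(
            f"fish {obs.fish_id}, assessor {obs.assessor_id}: negative day {obs.day}"
        )
    return violations


def compute_qi(obs: SensoryObservation, scheme: QIMScheme) -> QIRecord:
    """Sum the demerit points of one observation into a quality index."""
    violations = validate_observation(obs, scheme)
    if violations:
        raise ObservationError("; ".join(violations))
    qi = float(sum(int(obs.scores[name]) for name in scheme.parameter_names))
    return QIRecord(fish_id=obs.fish_id, assessor_id=obs.assessor_id, day=obs.day, qi=qi)


def read_observations(path: str | Path, scheme: QIMScheme) -> list[SensoryObservation]:
    """Read a wide observation table (fish_id, assessor_id, day, one column per parameter)."""
    df = pd.read_csv(path)
    required = ["fish_id", "assessor_id", "day"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ObservationError(f"observation table is missing columns {missing}")
    missing_params = [n for n in scheme.parameter_names if n not in df.columns]
    if missing_params:
        raise ObservationError(
            f"observation table is missing parameter columns {missing_params}"
        )
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        out.append(
            SensoryObservation(
                fish_id=str(rec["fish_id"]),
                assessor_id=str(rec["assessor_id"]),
                day=float(rec["day"]),
                scores={n: int(rec[n]) for n in scheme.parameter_names},
            )
        )
    return out


def write_observations(
    observations: Iterable[SensoryObservation], scheme: QIMScheme, path: str | Path
) -> None:
    rows = [
        {
            "fish_id": o.fish_id,
            "assessor_id": o.assessor_id,
            "day": o.day,
            **{n: o.scores.get(n) for n in scheme.parameter_names},
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def score_observations(
    observations: Iterable[SensoryObservation], scheme: QIMScheme
) -> pd.DataFrame:
    """Score a batch of observations into a QI table (fish_id, assessor_id, day, qi)."""
    records = [compute_qi(o, scheme) for o in observations]
    return pd.DataFrame(
        [
            {"fish_id": r.fish_id, "assessor_id": r.assessor_id, "day": r.day, "qi": r.qi}
            for r in records
        ]
    )
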