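"""Run configuration: one JSON file controls the whole pipeline.

Sections (all optional; omitted fields take the documented defaults):

.. code-block:: json

    {
      "seed": 0,
      "thresholds": {"mpg": 0.167, "mage": 0.072, "auc24": 13.889},
      "cohort": {"n_participants": 30, "...": "CohortSpec fields"},
      "individual_model": {"chains": 4, "...": "IndividualModelSpec fields"},
      "hierarchical": {"prob_threshold": 0.9, "...": "HierarchicalSpec fields"},
      "power": {"n_simulations": 200, "...": "PowerConfig fields"},
      "classification": {"prob_threshold": 0.8},
      "metrics": {"min_coverage": 0.7, "mage_direction": "both", "mage_sd_ddof": 1}
    }

Unknown keys raise a :class:`~nof1cgm.types.ValidationError` naming the
offending field, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

from nof1cgm.bayes import IndividualModelSpec
from nof1cgm.hierarchical import HierarchicalSpec
from nof1cgm.power import PowerConfig
from nof1cgm.simulate import CohortSpec
from nof1cgm.types import Thresholds, ValidationError


@dataclass(frozen=True)
class MetricsConfig:
    min_coverage: float = 0.7
    mage_direction: str = "both"
    mage_sd_ddof: int = 1

    def __post_init__(self):
        if not 0 <= self.min_coverage <= 1:
            raise ValidationError("metrics.min_coverage must be in [0, 1]")
        if self.mage_direction not in ("both", "first"):
            raise ValidationError("metrics.mage_direction must be 'both' or 'first'")


@dataclass(frozen=True)
class ClassificationConfig:
    prob_threshold: float = 0.80

    def __post_init__(self):
        if not 0 < self.prob_threshold < 1:
            raise ValidationError("classification.prob_threshold must be in (0, 1)")


def _build(cls, payload: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ValidationError(
            f"config section {section!r}: unknown field(s) {sorted(unknown)}"
        )
    if cls is CohortSpec and "start_date" in payload:
        payload = {**payload, "start_date": dt.date.fromisoformat(payload["start_date"])}
    if cls is CohortSpec and "mixture" in payload:
        payload = {**payload, "mixture": tuple(payload["mixture"])}
    try:
        return cls(**payload)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"config section {section!r}: {err}") from err


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    individual_model: IndividualModelSpec = field(default_factory=IndividualModelSpec)
    hierarchical: HierarchicalSpec = field(default_factory=HierarchicalSpec)
    power: PowerConfig = field(default_factory=PowerConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        sections = {
            "thresholds": Thresholds,
            "cohort": CohortSpec,
            "individual_model": IndividualModelSpec,
            "hierarchical": HierarchicalSpec,
            "power": PowerConfig,
            "classification": ClassificationConfig,
            "metrics": MetricsConfig,
        }
        unknown = set(payload) - set(sections) - {"seed"}
        if unknown:
            raise ValidationError(f"config: unknown section(s) {sorted(unknown)}")
        seed = int(payload.get("seed", 0))
        kwargs = {"seed": seed}
        for name, klass in sections.items():
            section = dict(payload.get(name, {}))
            # the top-level seed feeds every stage unless overridden
            if "seed" in {f.name for f in dataclasses.fields(klass)}:
                section.setdefault("seed", seed)
            kwargs[name] = _build(klass, section, name)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as err:
            raise ValidationError(f"{path}: invalid JSON ({err})") from err
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
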