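"""Questionnaire schema: domains, questions, items, raw ranges, weights.

A multi-domain PRO (patient-reported outcome) instrument is described by a
:class:`QuestionnaireSchema`: an ordered list of domains, each holding items
grouped into questions, with per-item raw score ranges and weights and a
per-domain weight for the total score.  Domain and total scores are always
reported on a normalised 0-100 scale (best = 100).

The bundled :func:`default_schema` is a structural stand-in for a sarcopenia
quality-of-life instrument — 7 domains, 22 questions, 55 items, raw item range
1-4, equal weights, with the Fears domain holding a single question.  It is
NOT the licensed SarQoL scoring algorithm: the published item wording and
weights are copyrighted and must be supplied by the user as a schema JSON if
faithful scoring is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .exceptions import SchemaError

#: Fixed worst-to-best ordering of the 7-point global rating-of-change anchor.
ANCHOR_LEVELS: tuple[str, ...] = (
    "much worse",
    "worse",
    "slightly worse",
    "about the same",
    "slightly better",
    "better",
    "much better",
)


@dataclass(frozen=True)
class ItemSpec:
    """A single raw item: identifier, parent question, raw range and weight."""

    item_id: str
    question_id: str
    minimum: float = 1.0
    maximum: float = 4.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.maximum <= self.minimum:
            raise SchemaError(
                f"item {self.item_id!r}: maximum ({self.maximum}) must exceed "
                f"minimum ({self.minimum})"
            )
        if self.weight <= 0:
            raise SchemaError(f"item {self.item_id!r}: weight must be strictly positive")


@dataclass(frozen=True)
class DomainSpec:
    """A named domain: ordered items and the domain weight in the total score."""

    name: str
    items: tuple[ItemSpec, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.items:
            raise SchemaError(f"domain {self.name!r} has no items")
        if self.weight <= 0:
            raise SchemaError(f"domain {self.name!r}: weight must be strictly positive")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def question_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for it in self.items:
            if it.question_id not in seen:
                seen.append(it.question_id)
        return tuple(seen)

    @property
    def n_questions(self) -> int:
        return len(self.question_ids)


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Full instrument description.

    Invariants enforced at construction: item ids unique across domains,
    strictly positive weights, exactly 7 anchor labels ordered worst to best.
    """

    instrument_name: str
    domains: tuple[DomainSpec, ...]
    anchor_labels: tuple[str, ...] = ANCHOR_LEVELS

    def __post_init__(self) -> None:
        if not self.domains:
            raise SchemaError("schema must define at least one domain")
        ids: list[str] = []
        for dom in self.domains:
            ids.extend(dom.item_ids)
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item ids across domains: {sorted(dupes)}")
        if len(self.anchor_labels) != 7:
            raise SchemaError(
                f"exactly 7 anchor labels required, got {len(self.anchor_labels)}"
            )
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            raise SchemaError("domain names must be unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.domains)

    @property
    def item_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for d in self.domains:
            out.extend(d.item_ids)
        return tuple(out)

    def domain(self, name: str) -> DomainSpec:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "instrument_name": self.instrument_name,
            "anchor_labels": list(self.anchor_labels),
            "domains": [
                {
                    "name": d.name,
                    "weight": d.weight,
                    "items": [
                        {
                            "item_id": it.item_id,
                            "question_id": it.question_id,
                            "minimum": it.minimum,
                            "maximum": it.maximum,
                            "weight": it.weight,
                        }
                        for it in d.items
                    ],
                }
                for d in self.domains
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "QuestionnaireSchema":
        try:
            domains = tuple(
                DomainSpec(
                    name=d["name"],
                    weight=d.get("weight", 1.0),
                    items=tuple(
                        ItemSpec(
                            item_id=it["item_id"],
                            question_id=it["question_id"],
                            minimum=it.get("minimum", 1.0),
                            maximum=it.get("maximum", 4.0),
                            weight=it.get("weight", 1.0),
                        )
                        for it in d["items"]
                    ),
                )
                for d in data["domains"]
            )
            return cls(
                instrument_name=data["instrument_name"],
                domains=domains,
                anchor_labels=tuple(data.get("anchor_labels", ANCHOR_LEVELS)),
            )
        except KeyError as exc:  # pragma: no cover - message formatting
            raise SchemaError(f"schema JSON missing required key: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuestionnaireSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


# question -> number of items, per domain, for the stand-in instrument:
# 7 domains, 22 questions, 55 items in total, Fears with a single question.
_DEFAULT_STRUCTURE: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("physical_mental_health", (3, 3, 2, 2)),
    ("locomotion", (2, 3, 2, 2)),
    ("body_composition", (3, 2, 2)),
    ("functionality", (3, 3, 3, 3, 2)),
    ("activities_daily_living", (3, 3, 3)),
    ("leisure_activities", (3, 2)),
    ("fears", (1,)),
)


def default_schema() -> QuestionnaireSchema:
    """Structural stand-in schema: 7 domains / 22 questions / 55 items, range 1-4.

    Equal item, question and domain weights.  Numerically generic — not the
    licensed instrument's scoring.
    """
    domains: list[DomainSpec] = []
    qnum = 0
    for name, question_sizes in _DEFAULT_STRUCTURE:
        items: list[ItemSpec] = []
        for n_items in question_sizes:
            qnum += 1
            qid = f"q{qnum:02d}"
            for j in range(1, n_items + 1):
                items.append(ItemSpec(item_id=f"{qid}_i{j}", question_id=qid))
        domains.append(DomainSpec(name=name, items=tuple(items)))
    return QuestionnaireSchema(instrument_name="standin_sarcopenia_qol",
                               domains=tuple(domains))
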