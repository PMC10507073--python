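"""Clinical knowledge base: per-concept state cutoffs and trend parameters.

A knowledge base holds, for each monitored clinical concept (a lab test such
as creatinine or a bedside chart item such as heart rate), an ordered set of
named value states (e.g. Hypothermia / Normal / Fever), the minimal change
``gradient_delta`` regarded as a genuine trend, and the window
``stable_hours`` within which a sub-threshold change is called Stable.

The default knowledge base bundled with the package covers 17 readmission-
related concepts: 12 low-frequency lab tests and 5 high-frequency chart
items. State intervals are half-open and lower-inclusive, ``[min, max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

GRADIENT_SYMBOLS = ("Increasing", "Decreasing", "Stable")


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    """State and trend definitions for one clinical concept."""

    name: str
    source: str              # "chart" or "lab"
    unit: str
    state_names: tuple[str, ...]
    cutoffs: tuple[float, ...]   # interior cutoffs, strictly increasing
    gradient_delta: float
    stable_hours: float
    itemid: int | None = None

    def __post_init__(self) -> None:
        if self.source not in ("chart", "lab"):
            raise ValueError(f"{self.name}: source must be 'chart' or 'lab'")
        if not 3 <= len(self.state_names) <= 6:
            raise ValueError(
                f"{self.name}: need 3-6 states, got {len(self.state_names)}"
            )
        if len(self.cutoffs) != len(self.state_names) - 1:
            raise ValueError(f"{self.name}: need one fewer cutoff than states")
        if not all(a < b for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError(f"{self.name}: cutoffs must be strictly increasing")
        if self.gradient_delta <= 0:
            raise ValueError(f"{self.name}: gradient_delta must be positive")
        if self.stable_hours <= 0:
            raise ValueError(f"{self.name}: stable_hours must be positive")

    def state_of(self, value: float) -> str:
        """Name of the half-open state interval containing ``value``."""
        if not np.isfinite(value):
            raise ValueError(f"{self.name}: non-finite value {value!r}")
        return self.state_names[int(np.searchsorted(self.cutoffs, value, side="right"))]


@dataclass
class KnowledgeBase:
    """Ordered collection of concept entries; order is the flattening tie-break."""

    entries: list[KnowledgeBaseEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate concept names in knowledge base")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> KnowledgeBaseEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def concept_names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def lab_concepts(self) -> list[KnowledgeBaseEntry]:
        return [e for e in self.entries if e.source == "lab"]

    @property
    def chart_concepts(self) -> list[KnowledgeBaseEntry]:
        return [e for e in self.entries if e.source == "chart"]

    def concept_rank(self, name: str) -> int:
        """Position of a concept in the canonical order (flattening tie-break)."""
        return self.concept_names.index(name)

    def by_itemid(self) -> dict[int, KnowledgeBaseEntry]:
        return {e.itemid: e for e in self.entries if e.itemid is not None}


def _entry_from_mapping(raw: dict) -> KnowledgeBaseEntry:
    states = raw["states"]
    names = tuple(s["name"] for s in states)
    cutoffs = []
    for prev, cur in zip(states, states[1:]):
        if "min" not in cur:
            raise ValueError(f"{raw['name']}: non-first state missing 'min'")
        if "max" in prev and float(prev["max"]) != float(cur["min"]):
            raise ValueError(f"{raw['name']}: state intervals must be contiguous")
        cutoffs.append(float(cur["min"]))
    return KnowledgeBaseEntry(
        name=raw["name"],
        source=raw["source"],
        unit=raw.get("unit", ""),
        state_names=names,
        cutoffs=tuple(cutoffs),
        gradient_delta=float(raw["gradient_delta"]),
        stable_hours=float(raw["stable_hours"]),
        itemid=int(raw["itemid"]) if "itemid" in raw else None,
    )


def load_knowledge_base(path: str | Path | None = None) -> KnowledgeBase:
    """Load a knowledge base from YAML; with no path, the bundled default.

    The bundled default encodes the 17-concept readmission knowledge base
    (12 lab + 5 chart concepts) with normal ranges, gradient thresholds and
    stable windows.
    """
    if path is None:
        text = (resources.files("icureadmit") / "data" / "kb.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "concepts" not in raw:
        raise ValueError("knowledge base YAML must contain a 'concepts' list")
    return KnowledgeBase([_entry_from_mapping(c) for c in raw["concepts"]])
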