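"""Ordinal scoring of intraventricular haemorrhage (IVH).

Two scales are provided as data-driven schemas:

* the classic Graeb scale: each lateral ventricle scores 1 (trace of blood)
  to 4 (full of blood and expanded), and the third and fourth ventricles
  score 1 (blood present) or 2 (filled with blood and expanded), for a
  maximum of 12;
* a modified Graeb scale over eight ventricular compartments (left/right
  frontal horn plus body, temporal horn, occipital horn; third; fourth),
  each scored 1-4 by quartile of blood filling (<=25 % ... >75 %), for a
  maximum of 32.  An optional expansion bonus (one point per expanded
  ventricle) can be enabled per schema; it raises the attainable maximum
  above 32 and is off by default.

Schemas are YAML files, not code: the compartment lists, fill thresholds and
bonus rules live in ``haemquant/schemas/`` and custom schemas can be loaded
from any path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "GraebSchema",
    "VentricularState",
    "load_schema",
    "graeb_score",
    "modified_graeb_score",
    "schema_max",
    "maximal_state",
    "empty_state",
    "generate_ventricular_state",
]

#: a fill fraction at or above this counts as "full"
FULL_FILL = 0.999


class SchemaError(ValueError):
    """Invalid scoring schema or state/schema mismatch."""


@dataclass(frozen=True)
class Compartment:
    """One scored ventricular compartment.

    ``rule`` selects how the fill fraction maps to points:

    * ``lateral_classic`` — 1 trace, 2 up to half filled, 3 more than half,
      4 full and expanded;
    * ``small_classic``  — 1 any blood, 2 full and expanded;
    * ``quartile``       — 1..4 by quartile of filling, expansion ignored.

    ``aggregates`` optionally names finer compartments whose mean fill stands
    in when the state does not carry this compartment directly (lets a state
    expressed in modified-Graeb compartments be scored with the classic
    scale).
    """

    name: str
    ventricle: str
    rule: str
    aggregates: tuple[str, ...] = ()


@dataclass(frozen=True)
class GraebSchema:
    name: str
    compartments: tuple[Compartment, ...]
    max_score: int
    expansion_bonus: int = 0  # points per expanded ventricle, on top of fill scores

    @property
    def ventricles(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.compartments:
            seen.setdefault(c.ventricle, None)
        return tuple(seen)


@dataclass(frozen=True)
class VentricularState:
    """Per-compartment blood fill fractions plus trace/expansion flags.

    ``fills`` maps compartment name -> fraction in [0, 1]; ``trace`` marks
    compartments where blood is present but the fraction is essentially zero
    (a distinct state on the classic scale); ``expanded`` maps ventricle
    name -> whether that ventricle is enlarged by the blood.
    """

    fills: Mapping[str, float]
    trace: frozenset[str] = frozenset()
    expanded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, f in self.fills.items():
            if not 0.0 <= f <= 1.0:
                raise SchemaError(f"fill fraction for {name} outside [0, 1]: {f}")
        object.__setattr__(self, "trace", frozenset(self.trace))
        object.__setattr__(self, "expanded", frozenset(self.expanded))

    def fill_of(self, comp: Compartment) -> float:
        if comp.name in self.fills:
            return float(self.fills[comp.name])
        if comp.aggregates:
            vals = [self.fills[a] for a in comp.aggregates if a in self.fills]
            if vals:
                return float(np.mean(vals))
        raise SchemaError(f"state does not cover compartment '{comp.name}'")

    def has_trace(self, comp: Compartment) -> bool:
        if comp.name in self.trace:
            return True
        return any(a in self.trace for a in comp.aggregates)

    def has_blood(self, comp: Compartment) -> bool:
        return self.fill_of(comp) > 0.0 or self.has_trace(comp)


def _schema_dir() -> Path:
    return Path(resources.files("haemquant").joinpath("schemas"))  # type: ignore[arg-type]


def load_schema(name_or_path: str) -> GraebSchema:
    """Load a scoring schema by bundled name (``classic``, ``mgs32``) or path."""
    path = Path(name_or_path)
    if not path.exists():
        path = _schema_dir() / f"{name_or_path}.yaml"
    if not path.exists():
        raise SchemaError(f"unknown schema '{name_or_path}'")
    raw = yaml.safe_load(path.read_text())
    comps = tuple(
        Compartment(
            name=c["name"],
            ventricle=c["ventricle"],
            rule=c["rule"],
            aggregates=tuple(c.get("aggregates", ())),
        )
        for c in raw["compartments"]
    )
    schema = GraebSchema(
        name=raw["name"],
        compartments=comps,
        max_score=int(raw["max_score"]),
        expansion_bonus=int(raw.get("expansion_bonus", 0)),
    )
    declared = schema.max_score + schema.expansion_bonus * len(schema.ventricles)
    if schema_max(schema) != declared:
        raise SchemaError(
            f"schema '{schema.name}' maximal state scores {schema_max(schema)}, "
            f"declared maximum is {declared}"
        )
    return schema


_CLASSIC: GraebSchema | None = None
_MGS32: GraebSchema | None = None


def classic_schema() -> GraebSchema:
    global _CLASSIC
    if _CLASSIC is None:
        _CLASSIC = load_schema("classic")
    return _CLASSIC


def mgs32_schema() -> GraebSchema:
    global _MGS32
    if _MGS32 is None:
        _MGS32 = load_schema("mgs32")
    return _MGS32


def _score_compartment(comp: Compartment, state: VentricularState) -> int:
    fill = state.fill_of(comp)
    expanded = comp.ventricle in state.expanded
    if comp.rule == "lateral_classic":
        if fill >= FULL_FILL and expanded:
            return 4
        if fill > 0.5:
            return 3
        if fill > 0.0:
            return 1 if state.has_trace(comp) and fill <= 0.05 else 2
        return 1 if state.has_trace(comp) else 0
    if comp.rule == "small_classic":
        if fill >= FULL_FILL and expanded:
            return 2
        return 1 if state.has_blood(comp) else 0
    if comp.rule == "quartile":
        if fill <= 0.0:
            return 1 if state.has_trace(comp) else 0
        if fill <= 0.25:
            return 1
        if fill <= 0.5:
            return 2
        if fill <= 0.75:
            return 3
        return 4
    raise SchemaError(f"unknown scoring rule '{comp.rule}'")


def _check_state(state: VentricularState, schema: GraebSchema) -> None:
    missing = []
    for comp in schema.compartments:
        try:
            state.fill_of(comp)
        except SchemaError:
            missing.append(comp.name)
    if missing:
        raise SchemaError(
            f"state is missing compartments required by schema "
            f"'{schema.name}': {', '.join(missing)}"
        )
    for v in state.expanded:
        agg = [c for c in schema.compartments if c.ventricle == v]
        if agg:
            fills = [state.fill_of(c) for c in agg]
            if max(fills) <= 0.0 and not any(state.has_trace(c) for c in agg):
                raise SchemaError(f"ventricle '{v}' marked expanded without blood")


def score(state: VentricularState, schema: GraebSchema) -> int:
    """Total ordinal score of a ventricular state under a schema."""
    _check_state(state, schema)
    total = sum(_score_compartment(c, state) for c in schema.compartments)
    if schema.expansion_bonus:
        total += schema.expansion_bonus * sum(
            1 for v in schema.ventricles if v in state.expanded
        )
    return total


def graeb_score(state: VentricularState, schema: GraebSchema | None = None) -> int:
    """Classic Graeb score (0-12 with the default schema)."""
    return score(state, schema or classic_schema())


def modified_graeb_score(
    state: VentricularState, schema: GraebSchema | None = None
) -> int:
    """Modified Graeb score (0-32 with the default mgs32 schema)."""
    return score(state, schema or mgs32_schema())


def _direct_compartments(schema: GraebSchema) -> list[Compartment]:
    return list(schema.compartments)


def maximal_state(schema: GraebSchema) -> VentricularState:
    """The fully filled, fully expanded state for a schema."""
    return VentricularState(
        fills={c.name: 1.0 for c in schema.compartments},
        expanded=frozenset(schema.ventricles),
    )


def empty_state(schema: GraebSchema) -> VentricularState:
    return VentricularState(fills={c.name: 0.0 for c in schema.compartments})


def schema_max(schema: GraebSchema) -> int:
    """Score of the maximal state (validates printed scale maxima)."""
    state = maximal_state(schema)
    total = sum(_score_compartment(c, state) for c in schema.compartments)
    if schema.expansion_bonus:
        total += schema.expansion_bonus * len(schema.ventricles)
    return total


def generate_ventricular_state(
    seed: int,
    schema: GraebSchema | None = None,
    preset: str | None = None,
) -> VentricularState:
    """Draw a random (or preset) ventricular state for a schema.

    Random states share a per-subject severity level across compartments with
    compartment-level jitter, so that anatomically adjacent compartments fill
    together the way real IVH spreads; ``preset`` may be ``"empty"`` or
    ``"maximal"``.
    """
    schema = schema or mgs32_schema()
    if preset == "empty":
        return empty_state(schema)
    if preset == "maximal":
        return maximal_state(schema)
    if preset is not None:
        raise SchemaError(f"unknown preset '{preset}'")

    rng = np.random.default_rng(seed)
    severity = rng.beta(1.5, 2.5)
    fills = {}
    trace = set()
    for comp in schema.compartments:
        f = float(np.clip(severity + rng.normal(0.0, 0.2), 0.0, 1.0))
        if 0.0 < f < 0.03 and rng.random() < 0.5:
            trace.add(comp.name)
            f = 0.0
        fills[comp.name] = f
    expanded = set()
    for v in schema.ventricles:
        comps = [c for c in schema.compartments if c.ventricle == v]
        mean_fill = float(np.mean([fills[c.name] for c in comps]))
        if mean_fill > 0.8 and rng.random() < 0.7:
            expanded.add(v)
            for c in comps:
                fills[c.name] = 1.0
    return VentricularState(fills=fills, trace=frozenset(trace), expanded=frozenset(expanded))
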