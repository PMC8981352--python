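"""Data model for emergency readiness definitions.

A :class:`DefinitionSet` declares the resources a facility survey can record
and, on top of them, two readiness models:

* **clinical cascades** — per emergency, three ordered stages of care
  (*identify*, *treat*, *monitor-modify*), each a conjunction of
  alternative-groups of resources; and
* **signal functions** — per WHO clinical action, a tracer requirement whose
  satisfaction proxies capacity to perform the action.

Resource lists are data: they live in a YAML/JSON config file and are never
hard-coded in the engine. Proxy substitutions (e.g. electrical power standing
in for refrigeration) are modelled as extra alternatives inside a group, so
requirement satisfaction is a pure conjunction of disjunctions.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Any, Iterator

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import ReferentialIntegrityError, SchemaError, StructuralError

__all__ = [
    "Category",
    "FunctionType",
    "STAGES",
    "ANTIBIOTIC_DRUGS",
    "ResourceItem",
    "AlternativeGroup",
    "ResourceRequirement",
    "CascadeDefinition",
    "SignalFunctionDefinition",
    "DefinitionSet",
    "AntibioticValidation",
    "load_definitions",
    "save_definitions",
    "definitions_to_csv",
    "validate_antibiotic_definition",
    "default_definitions_path",
]

#: Cascade stages, in clinical order. Readiness through a stage is cumulative.
STAGES: tuple[str, str, str] = ("identify", "treat", "monitor_modify")

#: WHO three-step obstetric antibiotic escalation sequence.
ANTIBIOTIC_DRUGS: tuple[str, str, str] = ("ampicillin", "gentamicin", "metronidazole")


class Category(str, enum.Enum):
    drug = "drug"
    consumable = "consumable"
    durable = "durable"
    protocol = "protocol"


class FunctionType(str, enum.Enum):
    medical_treatment = "medical_treatment"
    manual_procedure = "manual_procedure"


class ResourceItem(BaseModel):
    """One recordable resource (drug, consumable, durable good or protocol)."""

    model_config = ConfigDict(frozen=True)

    resource_id: str
    label: str = ""
    category: Category

    @field_validator("resource_id")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("resource_id must be non-empty")
        return v.strip()


class AlternativeGroup(BaseModel):
    """A disjunction of resource tokens; possessing ANY one satisfies it.

    Proxies are simply additional alternatives (e.g. ``[refrigerator,
    electricity]`` encodes "power is an acceptable proxy for refrigeration").
    """

    model_config = ConfigDict(frozen=True)

    alternatives: tuple[str, ...]
    note: str = ""

    @field_validator("alternatives", mode="before")
    @classmethod
    def _coerce(cls, v: Any) -> tuple[str, ...]:
        if isinstance(v, str):
            v = [v]
        items = tuple(str(t).strip() for t in v)
        if not items or any(not t for t in items):
            raise ValueError("an alternative group needs at least one non-empty token")
        if len(set(items)) != len(items):
            raise ValueError(f"duplicate alternatives in group: {items}")
        return items

    @property
    def key(self) -> frozenset[str]:
        """Order-insensitive identity of the group, used for set comparisons."""
        return frozenset(self.alternatives)


class ResourceRequirement(BaseModel):
    """Conjunction of alternative-groups; ALL groups must be satisfied.

    An empty group list marks a skill-only requirement (e.g. identifying a
    haemorrhage needs no commodity); commodity-based surveys treat clinician
    skill as uniformly present, so a skill-only requirement is always met.
    """

    model_config = ConfigDict(frozen=True)

    groups: tuple[AlternativeGroup, ...] = ()
    skill_only: bool = False

    @model_validator(mode="before")
    @classmethod
    def _infer_skill_only(cls, data: Any) -> Any:
        if isinstance(data, dict):
            groups = data.get("groups") or ()
            inferred = len(groups) == 0
            declared = data.get("skill_only")
            if declared is not None and bool(declared) != inferred:
                raise ValueError(
                    "skill_only must be true exactly when the group list is empty"
                )
            data = {**data, "skill_only": inferred, "groups": groups}
        return data

    def tokens(self) -> Iterator[str]:
        for g in self.groups:
            yield from g.alternatives

    def group_keys(self) -> set[frozenset[str]]:
        return {g.key for g in self.groups}


class CascadeDefinition(BaseModel):
    """An emergency's three-stage cascade (identify, treat, monitor-modify)."""

    model_config = ConfigDict(frozen=True)

    emergency_id: str
    stage_requirements: tuple[ResourceRequirement, ...]

    @model_validator(mode="after")
    def _exactly_three_stages(self) -> "CascadeDefinition":
        if len(self.stage_requirements) != len(STAGES):
            raise StructuralError(
                f"cascade '{self.emergency_id}' has {len(self.stage_requirements)} "
                f"stage(s); exactly {len(STAGES)} required ({', '.join(STAGES)})"
            )
        return self

    def stage(self, k: int) -> ResourceRequirement:
        """1-based stage accessor (1=identify, 2=treat, 3=monitor-modify)."""
        if not 1 <= k <= len(STAGES):
            raise IndexError(f"stage must be in 1..{len(STAGES)}, got {k}")
        return self.stage_requirements[k - 1]


class SignalFunctionDefinition(BaseModel):
    """A WHO signal function: tracer items proxying one clinical action."""

    model_config = ConfigDict(frozen=True)

    function_id: str
    function_type: FunctionType
    tracer_requirement: ResourceRequirement
    linked_emergency_id: str


class DefinitionSet(BaseModel):
    """Validated bundle of resources, cascades and signal functions."""

    model_config = ConfigDict(frozen=True)

    version: str = "unversioned"
    resources: tuple[ResourceItem, ...]
    cascades: tuple[CascadeDefinition, ...]
    signal_functions: tuple[SignalFunctionDefinition, ...] = ()

    @model_validator(mode="after")
    def _check_integrity(self) -> "DefinitionSet":
        ids = [r.resource_id for r in self.resources]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructuralError(f"duplicate resource_id(s): {', '.join(dupes)}")
        eids = [c.emergency_id for c in self.cascades]
        if len(set(eids)) != len(eids):
            raise StructuralError("duplicate emergency_id in cascade definitions")
        fids = [f.function_id for f in self.signal_functions]
        if len(set(fids)) != len(fids):
            raise StructuralError("duplicate function_id in signal functions")

        declared = set(ids)
        for c in self.cascades:
            for stage_name, req in zip(STAGES, c.stage_requirements):
                dangling = [t for t in req.tokens() if t not in declared]
                if dangling:
                    raise ReferentialIntegrityError(
                        dangling, where=f"cascade '{c.emergency_id}' stage '{stage_name}'"
                    )
        for f in self.signal_functions:
            dangling = [t for t in f.tracer_requirement.tokens() if t not in declared]
            if dangling:
                raise ReferentialIntegrityError(
                    dangling, where=f"signal function '{f.function_id}'"
                )
            if f.linked_emergency_id not in set(eids):
                raise ReferentialIntegrityError(
                    [f.linked_emergency_id],
                    where=f"signal function '{f.function_id}' linked_emergency_id",
                )
        return self

    # -- lookups ---------------------------------------------------------

    @property
    def resource_ids(self) -> frozenset[str]:
        return frozenset(r.resource_id for r in self.resources)

    @property
    def emergency_ids(self) -> tuple[str, ...]:
        return tuple(c.emergency_id for c in self.cascades)

    def cascade(self, emergency_id: str) -> CascadeDefinition:
        for c in self.cascades:
            if c.emergency_id == emergency_id:
                return c
        raise KeyError(f"no cascade '{emergency_id}'")

    def signal_function(self, function_id: str) -> SignalFunctionDefinition:
        for f in self.signal_functions:
            if f.function_id == function_id:
                return f
        raise KeyError(f"no signal function '{function_id}'")

    def tracer_group_keys(self) -> list[frozenset[str]]:
        """Distinct tracer alternative-groups across all signal functions."""
        seen: list[frozenset[str]] = []
        for f in self.signal_functions:
            for g in f.tracer_requirement.groups:
                if g.key not in seen:
                    seen.append(g.key)
        return seen

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def req(r: ResourceRequirement) -> dict[str, Any]:
            return {
                "skill_only": r.skill_only,
                "groups": [
                    {"alternatives": list(g.alternatives), **({"note": g.note} if g.note else {})}
                    for g in r.groups
                ],
            }

        return {
            "version": self.version,
            "resources": [
                {"resource_id": r.resource_id, "label": r.label, "category": r.category.value}
                for r in self.resources
            ],
            "cascades": [
                {
                    "emergency_id": c.emergency_id,
                    "stages": {name: req(r) for name, r in zip(STAGES, c.stage_requirements)},
                }
                for c in self.cascades
            ],
            "signal_functions": [
                {
                    "function_id": f.function_id,
                    "function_type": f.function_type.value,
                    "linked_emergency_id": f.linked_emergency_id,
                    "tracer_requirement": req(f.tracer_requirement),
                }
                for f in self.signal_functions
            ],
        }


def _parse_definition_dict(raw: Any) -> DefinitionSet:
    if not isinstance(raw, dict):
        raise SchemaError("definition config must be a mapping at top level")
    for key in ("resources", "cascades"):
        if key not in raw:
            raise SchemaError(f"definition config missing top-level key '{key}'")
    try:
        cascades = []
        for c in raw["cascades"]:
            stages = c.get("stages")
            if stages is None:
                raise SchemaError(
                    f"cascade '{c.get('emergency_id', '?')}' missing 'stages' mapping"
                )
            missing = [s for s in STAGES if s not in stages]
            if missing:
                raise StructuralError(
                    f"cascade '{c.get('emergency_id', '?')}' missing stage(s): "
                    f"{', '.join(missing)}"
                )
            cascades.append(
                {
                    "emergency_id": c["emergency_id"],
                    "stage_requirements": [stages[s] for s in STAGES],
                }
            )
        return DefinitionSet(
            version=str(raw.get("version", "unversioned")),
            resources=raw["resources"],
            cascades=cascades,
            signal_functions=raw.get("signal_functions", ()),
        )
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"invalid definition config at '{loc}': {first['msg']}") from e


def load_definitions(path: str | Path) -> DefinitionSet:
    """Load and validate a definition config (YAML or JSON).

    Raises :class:`SchemaError` on parse/shape failures (naming the offending
    field, and line for YAML syntax errors), :class:`ReferentialIntegrityError`
    for dangling resource tokens, and :class:`StructuralError` for cascades
    without exactly three stages or duplicate identifiers.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.MarkedYAMLError as e:
        mark = e.problem_mark
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise SchemaError(f"cannot parse {path.name}{where}: {e.problem}") from e
    except yaml.YAMLError as e:
        raise SchemaError(f"cannot parse {path.name}: {e}") from e
    return _parse_definition_dict(raw)


def save_definitions(defs: DefinitionSet, path: str | Path) -> Path:
    """Write a definition set back to YAML; round-trips through ``load_definitions``."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(defs.to_dict(), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )
    return path


def definitions_to_csv(defs: DefinitionSet, path: str | Path | None = None) -> pd.DataFrame:
    """Flat audit export: one row per (requirement group, alternative).

    Columns: scope (cascade/signal_function), emergency_or_function, stage,
    group_index, alternative_resource_id. Skill-only stages emit a single row
    with an empty alternative so the audit trail stays complete.
    """
    rows: list[dict[str, Any]] = []

    def emit(scope: str, owner: str, stage: str, req: ResourceRequirement) -> None:
        if req.skill_only:
            rows.append(
                {"scope": scope, "emergency_or_function": owner, "stage": stage,
                 "group_index": 0, "alternative_resource_id": ""}
            )
            return
        for gi, g in enumerate(req.groups, start=1):
            for alt in g.alternatives:
                rows.append(
                    {"scope": scope, "emergency_or_function": owner, "stage": stage,
                     "group_index": gi, "alternative_resource_id": alt}
                )

    for c in defs.cascades:
        for name, req in zip(STAGES, c.stage_requirements):
            emit("cascade", c.emergency_id, name, req)
    for f in defs.signal_functions:
        emit("signal_function", f.function_id, "tracer", f.tracer_requirement)

    frame = pd.DataFrame(
        rows,
        columns=["scope", "emergency_or_function", "stage", "group_index",
                 "alternative_resource_id"],
    )
    if path is not None:
        frame.to_csv(path, index=False, lineterminator="\n")
    return frame


class AntibioticValidation(BaseModel):
    """Report from checking the antibiotic tracer against the WHO three-drug rule."""

    ok: bool
    n_groups: int
    missing: tuple[str, ...] = ()
    unexpected_groups: tuple[str, ...] = ()
    message: str = ""


def validate_antibiotic_definition(
    defs: DefinitionSet, function_id: str = "antibiotic"
) -> AntibioticValidation:
    """Check that the antibiotic tracer is the strict three-drug conjunction.

    Readiness to give parenteral antibiotics is operationalised as possessing
    ALL of ampicillin, gentamicin and metronidazole (the WHO escalation
    sequence), each as its own single-drug group. Any missing drug or extra
    group fails the check.
    """
    try:
        sf = defs.signal_function(function_id)
    except KeyError:
        return AntibioticValidation(
            ok=False, n_groups=0, missing=ANTIBIOTIC_DRUGS,
            message=f"no signal function '{function_id}' in definition set",
        )
    actual = [g.key for g in sf.tracer_requirement.groups]
    expected = [frozenset({d}) for d in ANTIBIOTIC_DRUGS]
    missing = tuple(d for d, k in zip(ANTIBIOTIC_DRUGS, expected) if k not in actual)
    unexpected = tuple(
        "|".join(sorted(k)) for k in actual if k not in expected
    )
    ok = not missing and not unexpected and len(actual) == 3
    if ok:
        msg = "antibiotic tracer matches the three-drug escalation definition"
    elif missing:
        msg = f"missing drug group(s): {', '.join(missing)}"
    else:
        msg = f"unexpected group(s): {', '.join(unexpected)}"
    return AntibioticValidation(
        ok=ok, n_groups=len(actual), missing=missing,
        unexpected_groups=unexpected, message=msg,
    )


def default_definitions_path() -> Path:
    """Path of the packaged default definition config."""
    return Path(__file__).parent / "data" / "default_definitions.yaml"
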