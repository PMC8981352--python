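"""Requirement satisfaction and per-facility readiness profiles.

Two readiness models are evaluated from the same inventory:

* **cascade readiness** — per emergency, cumulative booleans
  ready-through-stage-1/2/3, where being ready through stage k requires ALL
  resources of stages 1..k (a facility that could treat but not identify an
  emergency is not ready to treat it);
* **signal-function readiness** — binary satisfaction of each function's
  tracer requirement, plus the item-average service readiness index (SRI),
  the fraction of distinct tracer groups satisfied.

Clinician skill is uniformly assumed present: a skill-only requirement is
always satisfied. Satisfaction is monotone — adding resources to an
inventory can never un-satisfy any requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .definitions import (
    CascadeDefinition,
    DefinitionSet,
    ResourceRequirement,
    SignalFunctionDefinition,
    STAGES,
)
from .errors import EstimateError
from .inventory_io import FacilityCohort, FacilityInventory

__all__ = [
    "evaluate_requirement",
    "cascade_profile",
    "signal_readiness",
    "sri_index",
    "FacilityReadinessProfile",
    "score_facility",
    "score_cohort",
    "profile_frame",
]


def _present(inv: FacilityInventory | frozenset[str] | set[str]) -> frozenset[str]:
    if isinstance(inv, FacilityInventory):
        return inv.present_resources
    return frozenset(inv)


def evaluate_requirement(
    inv: FacilityInventory | set[str] | frozenset[str], req: ResourceRequirement
) -> bool:
    """True iff every alternative-group has at least one member present.

    A skill-only requirement (no groups) is satisfied by any inventory.
    """
    present = _present(inv)
    return all(any(alt in present for alt in g.alternatives) for g in req.groups)


def cascade_profile(
    inv: FacilityInventory | set[str] | frozenset[str], cascade: CascadeDefinition
) -> tuple[bool, bool, bool]:
    """Cumulative (ready-through-stage-1, -2, -3) for one emergency."""
    ready: list[bool] = []
    so_far = True
    for req in cascade.stage_requirements:
        so_far = so_far and evaluate_requirement(inv, req)
        ready.append(so_far)
    return tuple(ready)  # type: ignore[return-value]


def signal_readiness(
    inv: FacilityInventory | set[str] | frozenset[str], sf: SignalFunctionDefinition
) -> bool:
    """True iff the function's tracer requirement is satisfied."""
    return evaluate_requirement(inv, sf.tracer_requirement)


def sri_index(
    inv: FacilityInventory | set[str] | frozenset[str], defs: DefinitionSet
) -> Fraction:
    """Item-average readiness: satisfied tracer groups / all distinct tracer groups."""
    keys = defs.tracer_group_keys()
    if not keys:
        raise EstimateError("SRI undefined: definition set declares no tracer groups")
    present = _present(inv)
    satisfied = sum(1 for key in keys if any(alt in present for alt in key))
    return Fraction(satisfied, len(keys))


@dataclass(frozen=True)
class FacilityReadinessProfile:
    facility_id: str
    cascade_ready: dict[str, tuple[bool, bool, bool]]
    signal_ready: dict[str, bool]
    sri: Fraction


def score_facility(inv: FacilityInventory, defs: DefinitionSet) -> FacilityReadinessProfile:
    return FacilityReadinessProfile(
        facility_id=inv.facility_id,
        cascade_ready={c.emergency_id: cascade_profile(inv, c) for c in defs.cascades},
        signal_ready={f.function_id: signal_readiness(inv, f) for f in defs.signal_functions},
        sri=sri_index(inv, defs) if defs.signal_functions else Fraction(0),
    )


def score_cohort(cohort: FacilityCohort, defs: DefinitionSet) -> list[FacilityReadinessProfile]:
    if cohort.n == 0:
        raise EstimateError("cannot score an empty cohort")
    return [score_facility(f, defs) for f in cohort]


def profile_frame(cohort: FacilityCohort, defs: DefinitionSet) -> pd.DataFrame:
    """Facility x indicator 0/1 matrix (plus SRI), one row per facility."""
    rows = []
    for p in score_cohort(cohort, defs):
        row: dict[str, object] = {"facility_id": p.facility_id}
        for eid, ready in p.cascade_ready.items():
            for stage_name, ok in zip(STAGES, ready):
                row[f"{eid}_{stage_name}"] = int(ok)
        for fid, ok in p.signal_ready.items():
            row[f"sf_{fid}"] = int(ok)
        row["sri_index"] = float(p.sri)
        rows.append(row)
    return pd.DataFrame(rows)
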