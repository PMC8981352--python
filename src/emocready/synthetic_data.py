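"""Synthetic facility cohorts, including a deterministic replica fixture.

Published facility-survey tables print readiness as 1-decimal percentages
over a known cohort size. For n=23, consecutive counts differ by about 4.35
percentage points, so every printed percentage pins down a unique integer
facility count; :func:`recover_count` inverts the display rounding
exhaustively. :func:`build_paper_replica` turns those recovered counts into a
concrete 23-facility cohort by nested prefix assignment — the resource bundle
with target count k is present in facilities 1..k — so that scoring the
cohort through the ordinary pipeline reproduces every recovered count
exactly.

The replica uses disjoint abstract resource bundles per emergency (e.g.
``hypertension_treat_kit``) because the true cross-emergency sharing pattern
of real commodities is not recoverable from published marginals; shared-
resource behaviour is exercised by the scoring unit tests instead.

:func:`generate_random` produces seeded stochastic cohorts for property
testing: under ``nested_threshold`` mode each facility draws one latent
capacity u and holds every resource whose marginal availability is at least
u (richer facilities hold supersets of poorer ones); under ``independent``
mode resources are independent coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .definitions import (
    AlternativeGroup,
    CascadeDefinition,
    DefinitionSet,
    FunctionType,
    ResourceItem,
    ResourceRequirement,
    SignalFunctionDefinition,
)
from .errors import CountRecoveryError, GeneratorError
from .inventory_io import FacilityCohort, FacilityInventory
from .rounding import round1

__all__ = [
    "recover_count",
    "ReplicaCountSpec",
    "replica_definitions",
    "build_paper_replica",
    "GeneratorConfig",
    "generate_random",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20160101  # survey baseline year; fixed for provenance

REPLICA_N = 23

#: Published study marginals the replica reproduces: per signal function, the
#: printed tracer-possession percentage; per emergency, the printed
#: identification-stage drop-off, cumulative stage-2 readiness and
#: monitor-modify-stage drop-off. Stage-2 readiness is used directly (rather
#: than telescoping the printed stage drops) because individually rounded
#: drops need not telescope to a representable count.
REPLICA_PRINTED = {
    "signal_pct": {
        "antibiotic": 69.6,
        "uterotonic": 60.9,
        "anticonvulsant": 78.3,
        "retained_placenta_removal": 69.6,
        "rpoc_removal": 69.6,
    },
    "identify_drop": {
        "sepsis": 26.1,
        "haemorrhage": 0.0,
        "hypertension": 69.6,
        "retained_placenta": 0.0,
        "incomplete_abortion": 0.0,
    },
    "stage2_pct": {
        "sepsis": 47.8,
        "haemorrhage": 60.9,
        "hypertension": 26.1,
        "retained_placenta": 43.5,
        "incomplete_abortion": 56.5,
    },
    "monitor_drop": {
        "sepsis": 17.4,
        "haemorrhage": 47.8,
        "hypertension": 13.0,
        "retained_placenta": 34.8,
        "incomplete_abortion": 47.8,
    },
}

#: Emergencies whose identification stage rests on staff skill alone.
SKILL_ONLY_IDENTIFY = ("haemorrhage", "retained_placenta")

FUNCTION_TO_EMERGENCY = {
    "antibiotic": "sepsis",
    "uterotonic": "haemorrhage",
    "anticonvulsant": "hypertension",
    "retained_placenta_removal": "retained_placenta",
    "rpoc_removal": "incomplete_abortion",
}
MEDICAL_FUNCTIONS = ("antibiotic", "uterotonic", "anticonvulsant")


def recover_count(percent_printed: float, n: int) -> int:
    """Invert 1-decimal display rounding: the unique k with round1(100k/n) == printed.

    Raises :class:`CountRecoveryError` when no count matches (a transcription
    inconsistency) or when several do (n too large for unique inversion).
    """
    if n < 1:
        raise CountRecoveryError("cohort size must be >= 1")
    matches = [
        k for k in range(n + 1)
        if abs(round1(Fraction(100 * k, n)) - percent_printed) < 1e-9
    ]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise CountRecoveryError(
            f"no count in 0..{n} prints as {percent_printed}% at 1 decimal"
        )
    raise CountRecoveryError(
        f"{percent_printed}% over n={n} is ambiguous: counts {matches}"
    )


@dataclass(frozen=True)
class ReplicaCountSpec:
    """Facility counts the replica cohort must reproduce under scoring.

    ``stage_counts[e]`` are cumulative ready-through-stage-1/2/3 counts
    (weakly decreasing); ``tracer_counts[f]`` are tracer-possession counts.
    """

    n: int = REPLICA_N
    tracer_counts: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    n_csec: int = 10
    n_private: int = 4
    n_uganda: int = 6

    def __post_init__(self) -> None:
        for eid, (k1, k2, k3) in self.stage_counts.items():
            if not (self.n >= k1 >= k2 >= k3 >= 0):
                raise CountRecoveryError(
                    f"stage counts for {eid} not weakly decreasing in 0..{self.n}: "
                    f"{(k1, k2, k3)}"
                )
        for fid, k in self.tracer_counts.items():
            if not 0 <= k <= self.n:
                raise CountRecoveryError(f"tracer count for {fid} outside 0..{self.n}")

    @classmethod
    def from_printed_tables(cls) -> "ReplicaCountSpec":
        """Recover every count from the published 1-decimal marginals."""
        tracers = {
            fid: recover_count(pct, REPLICA_N)
            for fid, pct in REPLICA_PRINTED["signal_pct"].items()
        }
        stages = {}
        for eid in REPLICA_PRINTED["stage2_pct"]:
            k1 = recover_count(
                round1(Fraction(100) - Fraction(str(REPLICA_PRINTED["identify_drop"][eid]))),
                REPLICA_N,
            )
            k2 = recover_count(REPLICA_PRINTED["stage2_pct"][eid], REPLICA_N)
            # printed monitor-stage drop pins down the stage-2 -> stage-3 loss
            k3 = k2 - recover_count(REPLICA_PRINTED["monitor_drop"][eid], REPLICA_N)
            stages[eid] = (k1, k2, k3)
        return cls(tracer_counts=tracers, stage_counts=stages)


def _bundle_counts(spec: ReplicaCountSpec) -> dict[str, int]:
    counts: dict[str, int] = {}
    for eid, (k1, k2, k3) in spec.stage_counts.items():
        if eid not in SKILL_ONLY_IDENTIFY:
            counts[f"{eid}_identify_kit"] = k1
        counts[f"{eid}_treat_kit"] = k2
        counts[f"{eid}_monitor_kit"] = k3
    for fid, k in spec.tracer_counts.items():
        counts[f"{fid}_tracer_kit"] = k
    return counts


def replica_definitions(spec: ReplicaCountSpec | None = None) -> DefinitionSet:
    """Abstract definition set matching the replica's disjoint resource bundles."""
    spec = spec or ReplicaCountSpec.from_printed_tables()
    resources = [
        ResourceItem(resource_id=rid, label=rid.replace("_", " "), category="consumable")
        for rid in _bundle_counts(spec)
    ]

    def single(rid: str) -> ResourceRequirement:
        return ResourceRequirement(groups=(AlternativeGroup(alternatives=(rid,)),))

    cascades = []
    for eid in spec.stage_counts:
        identify = (
            ResourceRequirement()
            if eid in SKILL_ONLY_IDENTIFY
            else single(f"{eid}_identify_kit")
        )
        cascades.append(
            CascadeDefinition(
                emergency_id=eid,
                stage_requirements=(
                    identify, single(f"{eid}_treat_kit"), single(f"{eid}_monitor_kit")
                ),
            )
        )
    signal_functions = [
        SignalFunctionDefinition(
            function_id=fid,
            function_type=(
                FunctionType.medical_treatment
                if fid in MEDICAL_FUNCTIONS
                else FunctionType.manual_procedure
            ),
            linked_emergency_id=FUNCTION_TO_EMERGENCY[fid],
            tracer_requirement=single(f"{fid}_tracer_kit"),
        )
        for fid in spec.tracer_counts
    ]
    return DefinitionSet(
        version="replica-1.0.0",
        resources=tuple(resources),
        cascades=tuple(cascades),
        signal_functions=tuple(signal_functions),
    )


def _replica_attributes(spec: ReplicaCountSpec) -> list[tuple[str, str, str, bool]]:
    """(facility_id, country, ownership, csec) with fixed, documented assignment.

    Facilities 1..n_csec are C-section capable; 1..n_private are private; the
    Ugandan facilities are the last n_uganda of the C-section block (every
    Ugandan facility reports C-section capability; private facilities sit in
    the other country). The joint attribute x readiness distribution is one
    consistent completion, not an estimate.
    """
    if spec.n_uganda > spec.n_csec or spec.n_private > spec.n_csec - spec.n_uganda:
        raise GeneratorError("attribute counts incompatible with nested assignment")
    rows = []
    uganda_ids = set(range(spec.n_csec - spec.n_uganda + 1, spec.n_csec + 1))
    for i in range(1, spec.n + 1):
        rows.append(
            (
                f"F{i:02d}",
                "Uganda" if i in uganda_ids else "Kenya",
                "private" if i <= spec.n_private else "government",
                i <= spec.n_csec,
            )
        )
    return rows


def build_paper_replica(
    defs: DefinitionSet | None = None, spec: ReplicaCountSpec | None = None
) -> FacilityCohort:
    """Deterministic 23-facility cohort whose scored output hits every recovered count.

    Nested prefix assignment: the bundle with target count k is present in
    facilities 1..k, so cumulative stage counts fall out of the ordinary
    cumulative scoring logic with no per-facility bookkeeping.
    """
    spec = spec or ReplicaCountSpec.from_printed_tables()
    defs = defs or replica_definitions(spec)
    counts = _bundle_counts(spec)
    missing = set(counts) - set(defs.resource_ids)
    if missing:
        raise GeneratorError(
            f"definition set lacks replica bundle resource(s): {sorted(missing)}"
        )
    facilities = []
    for fid, country, ownership, csec in _replica_attributes(spec):
        rank = int(fid[1:])
        facilities.append(
            FacilityInventory(
                facility_id=fid,
                country=country,
                ownership=ownership,
                csec_capable=csec,
                present_resources=frozenset(
                    rid for rid, k in counts.items() if rank <= k
                ),
            )
        )
    return FacilityCohort(
        tuple(facilities),
        provenance="replica fixture: counts recovered from published 1-decimal marginals",
    )


class GeneratorConfig(BaseModel):
    """Configuration for seeded random cohorts."""

    model_config = ConfigDict(frozen=True)

    n_facilities: int = Field(gt=0)
    default_marginal: float = Field(default=0.7, ge=0.0, le=1.0)
    marginals: dict[str, float] = Field(default_factory=dict)
    mode: Literal["independent", "nested_threshold"] = "nested_threshold"
    seed: int = DEFAULT_SEED
    p_csec: float = Field(default=10 / 23, ge=0.0, le=1.0)
    p_private: float = Field(default=4 / 23, ge=0.0, le=1.0)
    p_uganda: float = Field(default=6 / 23, ge=0.0, le=1.0)


def generate_random(config: GeneratorConfig, defs: DefinitionSet) -> FacilityCohort:
    """Seeded random cohort over the definition set's declared resources.

    ``nested_threshold`` draws one latent capacity per facility, so resource
    sets are nested across facilities and stage readiness is automatically
    monotone-compatible; ``independent`` flips one coin per (facility,
    resource). Ugandan facilities are forced C-section capable, mirroring the
    study setting the generator emulates.
    """
    bad = {
        r: p for r, p in config.marginals.items()
        if not 0.0 <= p <= 1.0
    }
    if bad:
        raise GeneratorError(f"marginal probabilities outside [0, 1]: {bad}")
    unknown = set(config.marginals) - set(defs.resource_ids)
    if unknown:
        raise GeneratorError(f"marginals for undeclared resource(s): {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    resources = sorted(defs.resource_ids)
    p = np.array([config.marginals.get(r, config.default_marginal) for r in resources])
    n = config.n_facilities

    if config.mode == "nested_threshold":
        u = rng.uniform(size=n)
        have = u[:, None] <= p[None, :]
    else:
        have = rng.uniform(size=(n, len(resources))) <= p[None, :]

    csec = rng.uniform(size=n) < config.p_csec
    private = rng.uniform(size=n) < config.p_private
    uganda = rng.uniform(size=n) < config.p_uganda
    csec = csec | uganda  # all Ugandan facilities offer C-sections

    facilities = tuple(
        FacilityInventory(
            facility_id=f"S{i + 1:03d}",
            country="Uganda" if uganda[i] else "Kenya",
            ownership="private" if private[i] else "government",
            csec_capable=bool(csec[i]),
            present_resources=frozenset(
                r for r, h in zip(resources, have[i]) if h
            ),
        )
        for i in range(n)
    )
    return FacilityCohort(
        facilities,
        provenance=f"generated: mode={config.mode}, seed={config.seed}, n={n}",
    )
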