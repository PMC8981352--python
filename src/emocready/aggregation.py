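"""Population-level readiness indicators.

Turns scored facility profiles into the indicator family used to compare the
two readiness models:

* per-indicator facility proportions (counts over cohort size, carried as
  exact fractions; display rounding happens only when tables are written);
* per-emergency stage **drop-offs** — the percentage-point loss of ready
  facilities between successive cascade stages, with the stage-1 drop
  measured from 100%;
* unweighted **pooled means** across emergencies (each emergency counts
  equally) with sample standard deviations (n-1 denominator);
* **overestimation** — signal-function readiness minus cascade stage-2
  readiness, in percentage points; and
* stratified variants by level of care (C-section capability), ownership and
  country.

All arithmetic is exact until display: a pooled difference is computed from
counts (e.g. (16-11)/23 -> 21.7), never from pre-rounded percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .definitions import DefinitionSet, FunctionType
from .errors import EstimateError
from .inventory_io import FacilityCohort
from .rounding import round1
from .scoring import cascade_profile, signal_readiness

__all__ = [
    "ReadinessEstimate",
    "proportion_ready",
    "dropoff_by_stage",
    "pooled_mean",
    "sample_sd",
    "pooled_mean_sd",
    "overestimation",
    "stratify",
    "build_tables",
    "STRATUM_ATTRIBUTES",
]

STRATUM_ATTRIBUTES = ("csec_capable", "ownership", "country")


@dataclass(frozen=True)
class ReadinessEstimate:
    """count/denominator for one (population, indicator) pair."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise EstimateError(
                f"count {self.numerator} outside 0..{self.denominator}"
            )

    @property
    def percent(self) -> Fraction:
        """Exact percentage, 100 * count / n."""
        return Fraction(100 * self.numerator, self.denominator)

    @property
    def display(self) -> float:
        """Percentage rounded to 1 decimal, half away from zero."""
        return round1(self.percent)


Indicator = tuple  # ("signal", function_id) | ("cascade", emergency_id, stage)


def _indicator_flag(facility, defs: DefinitionSet, indicator: Indicator) -> bool:
    kind = indicator[0]
    if kind == "signal":
        return signal_readiness(facility, defs.signal_function(indicator[1]))
    if kind == "cascade":
        _, emergency_id, stage = indicator
        return cascade_profile(facility, defs.cascade(emergency_id))[stage - 1]
    raise ValueError(f"unknown indicator kind '{kind}'")


def proportion_ready(
    cohort: FacilityCohort, defs: DefinitionSet, indicator: Indicator
) -> ReadinessEstimate:
    """Facility proportion satisfying an indicator.

    ``indicator`` is ``("signal", function_id)`` or
    ``("cascade", emergency_id, stage)`` with stage in 1..3 (cumulative).
    """
    if cohort.n == 0:
        raise EstimateError("proportion undefined on an empty cohort")
    count = sum(1 for f in cohort if _indicator_flag(f, defs, indicator))
    return ReadinessEstimate(count, cohort.n)


def dropoff_by_stage(
    cohort: FacilityCohort, defs: DefinitionSet, emergency_id: str
) -> tuple[Fraction, Fraction, Fraction]:
    """Percentage-point readiness losses at each cascade stage.

    Stage-1 drop is 100 minus ready-through-stage-1; later drops are
    successive differences of cumulative readiness. Cumulative monotonicity
    guarantees every drop is non-negative, and the three drops plus final
    readiness telescope to exactly 100.
    """
    r = [
        proportion_ready(cohort, defs, ("cascade", emergency_id, k)).percent
        for k in (1, 2, 3)
    ]
    return (Fraction(100) - r[0], r[0] - r[1], r[1] - r[2])


def pooled_mean(values: Sequence[Fraction | float | int]) -> Fraction:
    """Unweighted arithmetic mean, exact."""
    vals = [Fraction(v) for v in values]
    if not vals:
        raise EstimateError("mean undefined on an empty sequence")
    return sum(vals, Fraction(0)) / len(vals)


def sample_sd(values: Sequence[Fraction | float | int]) -> float:
    """Sample standard deviation (n-1 denominator); exact variance, then sqrt."""
    vals = [Fraction(v) for v in values]
    if len(vals) < 2:
        raise EstimateError("sample SD undefined for fewer than two values")
    m = pooled_mean(vals)
    var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
    return math.sqrt(var)


def pooled_mean_sd(values: Sequence[Fraction | float | int]) -> tuple[Fraction, float]:
    return pooled_mean(values), sample_sd(values)


def overestimation(
    cohort: FacilityCohort, defs: DefinitionSet, function_id: str
) -> Fraction:
    """Signal-function readiness minus linked cascade stage-2 readiness (pp)."""
    sf = defs.signal_function(function_id)
    signal = proportion_ready(cohort, defs, ("signal", function_id)).percent
    stage2 = proportion_ready(
        cohort, defs, ("cascade", sf.linked_emergency_id, 2)
    ).percent
    return signal - stage2


def _stratum_order(attribute: str, values: Iterable) -> list:
    vals = list(dict.fromkeys(values))
    if attribute == "csec_capable":
        return sorted(vals, reverse=True)  # C-section capable first
    return sorted(vals)


def _stratum_label(attribute: str, value) -> str:
    if attribute == "csec_capable":
        return "csec" if value else "no_csec"
    return str(value)


def stratify(cohort: FacilityCohort, attribute: str) -> dict[str, FacilityCohort]:
    """Partition a cohort by a facility attribute.

    Returns ``{stratum label: sub-cohort}``; sub-cohort sizes sum to the
    cohort size. Raises if the attribute is unknown or blank on any facility.
    """
    if attribute not in STRATUM_ATTRIBUTES:
        raise EstimateError(
            f"unknown stratum attribute '{attribute}'; expected one of {STRATUM_ATTRIBUTES}"
        )
    values = []
    for f in cohort:
        v = getattr(f, attribute)
        if v is None or (isinstance(v, str) and not v.strip()):
            raise EstimateError(
                f"facility {f.facility_id} has no value for attribute '{attribute}'"
            )
        values.append(v)
    out: dict[str, FacilityCohort] = {}
    for v in _stratum_order(attribute, values):
        members = tuple(f for f in cohort if getattr(f, attribute) == v)
        out[_stratum_label(attribute, v)] = FacilityCohort(
            members, provenance=f"{cohort.provenance} | {attribute}={v}"
        )
    return out


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def _pairs_by_type(defs: DefinitionSet) -> list:
    """(signal function, linked emergency) pairs, medical first, defs order."""
    medical = [f for f in defs.signal_functions if f.function_type is FunctionType.medical_treatment]
    manual = [f for f in defs.signal_functions if f.function_type is FunctionType.manual_procedure]
    return medical + manual


def _comparison_rows(cohort: FacilityCohort, defs: DefinitionSet) -> pd.DataFrame:
    """Signal vs cascade stage-2 readiness per emergency, with pooled rows."""
    rows = []
    per_type: dict[str, list[tuple[Fraction, Fraction]]] = {"medical": [], "manual": []}
    for sf in _pairs_by_type(defs):
        sig = proportion_ready(cohort, defs, ("signal", sf.function_id)).percent
        casc = proportion_ready(
            cohort, defs, ("cascade", sf.linked_emergency_id, 2)
        ).percent
        kind = (
            "medical" if sf.function_type is FunctionType.medical_treatment else "manual"
        )
        per_type[kind].append((sig, casc))
        rows.append(
            {
                "label": sf.linked_emergency_id,
                "signal_function": sf.function_id,
                "n": cohort.n,
                "signal_pct": float(sig),
                "cascade_stage2_pct": float(casc),
                "overestimation_pp": float(sig - casc),
            }
        )

    def pooled_row(label: str, pairs) -> dict:
        sig = pooled_mean([p[0] for p in pairs])
        casc = pooled_mean([p[1] for p in pairs])
        return {
            "label": label, "signal_function": "", "n": cohort.n,
            "signal_pct": float(sig), "cascade_stage2_pct": float(casc),
            "overestimation_pp": float(sig - casc),
        }

    all_pairs = per_type["medical"] + per_type["manual"]
    rows.append(pooled_row("medical_pooled", per_type["medical"]))
    rows.append(pooled_row("manual_pooled", per_type["manual"]))
    rows.append(pooled_row("overall_pooled", all_pairs))
    return pd.DataFrame(rows)


def _dropoff_rows(cohort: FacilityCohort, defs: DefinitionSet) -> pd.DataFrame:
    """Drop-off by cascade and stage, with pooled mean and SD rows.

    Layout mirrors the printed drop-off table: the ``pooled_mean`` row holds
    per-stage pooled means, the overall pooled mean (of the five per-emergency
    means) in ``mean_drop`` and the mean of the per-emergency SDs in
    ``sd_drop``; the ``sd`` row holds per-stage SDs and, in ``mean_drop``, the
    sample SD of the per-emergency means.
    """
    eids = [sf.linked_emergency_id for sf in _pairs_by_type(defs)]
    drops = {eid: dropoff_by_stage(cohort, defs, eid) for eid in eids}
    rows = []
    emergency_means, emergency_sds = [], []
    for eid in eids:
        d = drops[eid]
        m = pooled_mean(d)
        s = sample_sd(d)
        emergency_means.append(m)
        emergency_sds.append(s)
        rows.append(
            {"label": eid, "identify_drop": float(d[0]), "treat_drop": float(d[1]),
             "monitor_modify_drop": float(d[2]), "mean_drop": float(m), "sd_drop": s}
        )
    stage_means = [pooled_mean([drops[e][k] for e in eids]) for k in range(3)]
    stage_sds = [sample_sd([drops[e][k] for e in eids]) for k in range(3)]
    rows.append(
        {"label": "pooled_mean",
         "identify_drop": float(stage_means[0]), "treat_drop": float(stage_means[1]),
         "monitor_modify_drop": float(stage_means[2]),
         "mean_drop": float(pooled_mean(emergency_means)),
         "sd_drop": float(pooled_mean(emergency_sds))}
    )
    rows.append(
        {"label": "sd",
         "identify_drop": stage_sds[0], "treat_drop": stage_sds[1],
         "monitor_modify_drop": stage_sds[2],
         "mean_drop": sample_sd(emergency_means), "sd_drop": float("nan")}
    )
    return pd.DataFrame(rows)


def _stratified_comparison(
    cohort: FacilityCohort, defs: DefinitionSet, attribute: str
) -> pd.DataFrame:
    """Overestimation per emergency, overall and per stratum of one attribute."""
    strata = stratify(cohort, attribute)
    columns = {"all": cohort} | strata
    rows = [
        {"label": "n", **{name: float(sub.n) for name, sub in columns.items()}}
    ]
    per_col: dict[str, list[Fraction]] = {name: [] for name in columns}
    for sf in _pairs_by_type(defs):
        row: dict[str, object] = {"label": sf.linked_emergency_id}
        for name, sub in columns.items():
            if sub.n == 0:
                row[name] = float("nan")
                continue
            diff = overestimation(sub, defs, sf.function_id)
            per_col[name].append(diff)
            row[name] = float(diff)
        rows.append(row)
    rows.append(
        {"label": "pooled_mean",
         **{name: (float(pooled_mean(v)) if v else float("nan"))
            for name, v in per_col.items()}}
    )
    return pd.DataFrame(rows)


def _stratified_dropoff(
    cohort: FacilityCohort, defs: DefinitionSet, attribute: str
) -> pd.DataFrame:
    """Mean drop-off across the three stages per emergency, by stratum."""
    strata = stratify(cohort, attribute)
    columns = {"all": cohort} | strata
    rows = [
        {"label": "n", **{name: float(sub.n) for name, sub in columns.items()}}
    ]
    per_col: dict[str, list[Fraction]] = {name: [] for name in columns}
    for sf in _pairs_by_type(defs):
        eid = sf.linked_emergency_id
        row: dict[str, object] = {"label": eid}
        for name, sub in columns.items():
            if sub.n == 0:
                row[name] = float("nan")
                continue
            m = pooled_mean(dropoff_by_stage(sub, defs, eid))
            per_col[name].append(m)
            row[name] = float(m)
        rows.append(row)
    rows.append(
        {"label": "overall_mean",
         **{name: (float(pooled_mean(v)) if v else float("nan"))
            for name, v in per_col.items()}}
    )
    rows.append(
        {"label": "overall_sd",
         **{name: (sample_sd(v) if len(v) >= 2 else float("nan"))
            for name, v in per_col.items()}}
    )
    return pd.DataFrame(rows)


def build_tables(
    cohort: FacilityCohort,
    defs: DefinitionSet,
    strata: Sequence[str] = (),
) -> dict[str, pd.DataFrame]:
    """Assemble the full result-table family.

    Returns ``comparison`` (signal vs cascade stage 2 with overestimation),
    ``dropoff`` (by cascade and stage with pooled rows) and, per requested
    attribute, ``comparison_by_<attr>`` and ``dropoff_by_<attr>``.
    """
    tables = {
        "comparison": _comparison_rows(cohort, defs),
        "dropoff": _dropoff_rows(cohort, defs),
    }
    for attribute in strata:
        tables[f"comparison_by_{attribute}"] = _stratified_comparison(
            cohort, defs, attribute
        )
        tables[f"dropoff_by_{attribute}"] = _stratified_dropoff(cohort, defs, attribute)
    return tables
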