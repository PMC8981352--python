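"""Read facility inventories/attributes and write result tables.

Input files are plain CSV (UTF-8, header row). The inventory comes in either

* **long form** — columns ``facility_id, resource_id, present`` (0/1), one row
  per facility x resource observation (possibly repeated across units/wards);
  or
* **wide form** — ``facility_id`` plus one 0/1 column per resource.

Presence is collapsed to the facility level regardless of unit: duplicate
long-form rows are fine as long as they agree; contradictory flags are an
error. A resource never mentioned for a facility counts as not present (a
coverage warning lists unreported resources, since absence of a record is not
the same as a measured absence).

Facility attributes live in a separate CSV with columns
``facility_id, country, ownership, csec_capable``; reported caesarean-section
capability is the level-of-care field (proxy for CEmOC designation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .definitions import DefinitionSet
from .errors import ConflictingRecordError, InventoryError, UnknownResourceError
from .rounding import fmt1

__all__ = [
    "FacilityInventory",
    "FacilityCohort",
    "read_inventory",
    "write_table",
    "write_cohort",
    "ATTRIBUTE_COLUMNS",
]

ATTRIBUTE_COLUMNS = ("facility_id", "country", "ownership", "csec_capable")
OWNERSHIP_VALUES = ("government", "private")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


@dataclass(frozen=True)
class FacilityInventory:
    """One facility: attributes plus the set of resources present on-site."""

    facility_id: str
    country: str
    ownership: str
    csec_capable: bool
    present_resources: frozenset[str] = frozenset()

    def with_resources(self, resources: frozenset[str]) -> "FacilityInventory":
        return FacilityInventory(
            self.facility_id, self.country, self.ownership,
            self.csec_capable, frozenset(resources),
        )


@dataclass(frozen=True)
class FacilityCohort:
    """Ordered collection of facilities with a provenance note."""

    facilities: tuple[FacilityInventory, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [f.facility_id for f in self.facilities]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InventoryError(f"duplicate facility_id(s): {', '.join(dupes)}")

    @property
    def n(self) -> int:
        return len(self.facilities)

    def __iter__(self):
        return iter(self.facilities)


def _parse_flag(value: object, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise InventoryError(f"{context}: cannot interpret '{value}' as a 0/1 flag")


def _read_attributes(path: str | Path) -> pd.DataFrame:
    attrs = pd.read_csv(path, dtype=str)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in attrs.columns]
    if missing:
        raise InventoryError(
            f"attributes file missing column(s): {', '.join(missing)}"
        )
    if attrs["facility_id"].duplicated().any():
        dupes = attrs.loc[attrs["facility_id"].duplicated(), "facility_id"].tolist()
        raise InventoryError(f"duplicate facility_id in attributes: {dupes}")
    for col in ("country", "ownership"):
        blank = attrs[col].isna() | (attrs[col].str.strip() == "")
        if blank.any():
            bad = attrs.loc[blank, "facility_id"].tolist()
            raise InventoryError(f"missing {col} for facility {bad[0]}")
    bad_own = ~attrs["ownership"].isin(OWNERSHIP_VALUES)
    if bad_own.any():
        raise InventoryError(
            "ownership must be one of "
            f"{OWNERSHIP_VALUES}; got {sorted(attrs.loc[bad_own, 'ownership'].unique())}"
        )
    return attrs


def _presence_long(
    inv: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Facility-level (present, mentioned) resource sets from long-form rows."""
    present: dict[str, set[str]] = {}
    mentioned: dict[str, set[str]] = {}
    flags = inv.assign(
        _flag=[
            _parse_flag(v, f"facility {f}, resource {r}")
            for f, r, v in zip(inv["facility_id"], inv["resource_id"], inv["present"])
        ]
    )
    grouped = flags.groupby(["facility_id", "resource_id"])["_flag"]
    conflicts = grouped.nunique()
    if (conflicts > 1).any():
        fac, res = conflicts[conflicts > 1].index[0]
        raise ConflictingRecordError(
            f"facility {fac}: conflicting presence flags for resource '{res}'"
        )
    # any unit having the item => facility-level presence
    for (fac, res), flag in grouped.max().items():
        mentioned.setdefault(str(fac), set()).add(str(res))
        present.setdefault(str(fac), set())
        if flag:
            present[str(fac)].add(str(res))
    return present, mentioned


def _presence_wide(
    inv: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    if inv["facility_id"].duplicated().any():
        dupes = inv.loc[inv["facility_id"].duplicated(), "facility_id"].tolist()
        raise InventoryError(f"duplicate facility rows in wide-form inventory: {dupes}")
    present: dict[str, set[str]] = {}
    mentioned: dict[str, set[str]] = {}
    resource_cols = [c for c in inv.columns if c != "facility_id"]
    for _, row in inv.iterrows():
        fac = str(row["facility_id"])
        mentioned[fac] = set(resource_cols)
        present[fac] = {
            c for c in resource_cols
            if _parse_flag(row[c], f"facility {fac}, resource {c}")
        }
    return present, mentioned


def read_inventory(
    inventory_path: str | Path,
    attributes_path: str | Path,
    defs: DefinitionSet,
    unknown_policy: Literal["error", "warn_drop"] = "error",
) -> FacilityCohort:
    """Read an inventory CSV (long or wide form) plus attributes into a cohort.

    ``unknown_policy`` controls resource tokens absent from ``defs``:
    ``"error"`` rejects the file listing the tokens; ``"warn_drop"`` warns and
    drops them.
    """
    attrs = _read_attributes(attributes_path)
    inv = pd.read_csv(inventory_path, dtype=str)
    if inv.empty and "facility_id" not in inv.columns:
        present: dict[str, set[str]] = {}
        mentioned: dict[str, set[str]] = {}
    elif {"facility_id", "resource_id", "present"} <= set(inv.columns):
        present, mentioned = _presence_long(inv)
    elif "facility_id" in inv.columns:
        present, mentioned = _presence_wide(inv)
    else:
        raise InventoryError(
            "inventory file must have long-form columns "
            "(facility_id, resource_id, present) or wide form (facility_id + resources)"
        )

    unknown_facilities = sorted(set(present) - set(attrs["facility_id"]))
    if unknown_facilities:
        raise InventoryError(
            f"inventory mentions facilities absent from attributes: {unknown_facilities}"
        )

    declared = defs.resource_ids
    all_tokens = set().union(*mentioned.values()) if mentioned else set()
    unknown = sorted(all_tokens - declared)
    if unknown:
        if unknown_policy == "error":
            raise UnknownResourceError(unknown)
        warnings.warn(
            f"dropping {len(unknown)} unknown resource token(s): {', '.join(unknown)}",
            stacklevel=2,
        )

    facilities = []
    for _, row in attrs.iterrows():
        fac = str(row["facility_id"])
        resources = frozenset(present.get(fac, set()) & declared)
        unreported = declared - mentioned.get(fac, set())
        if fac in mentioned and unreported:
            warnings.warn(
                f"facility {fac}: {len(unreported)} declared resource(s) unreported; "
                "treated as not present",
                stacklevel=2,
            )
        facilities.append(
            FacilityInventory(
                facility_id=fac,
                country=str(row["country"]).strip(),
                ownership=str(row["ownership"]).strip(),
                csec_capable=_parse_flag(row["csec_capable"], f"facility {fac} csec_capable"),
                present_resources=resources,
            )
        )
    return FacilityCohort(
        facilities=tuple(facilities),
        provenance=f"read from {Path(inventory_path).name} + {Path(attributes_path).name}",
    )


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as deterministic CSV.

    Float cells are printed at 1 decimal (half away from zero), integer cells
    as integers, missing cells as ``NA``. Byte output is a pure function of
    the table contents.
    """
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]) or out[col].dtype == object:
            out[col] = [
                "NA" if (v is None or (isinstance(v, float) and np.isnan(v)))
                else (fmt1(v) if isinstance(v, float) else str(v))
                for v in out[col]
            ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_cohort(
    cohort: FacilityCohort,
    inventory_path: str | Path,
    attributes_path: str | Path,
    defs: DefinitionSet | None = None,
) -> None:
    """Write a cohort as long-form inventory + attributes CSVs.

    If ``defs`` is given, every declared resource gets an explicit 0/1 row per
    facility, so a read-back round-trips presence flags exactly.
    """
    resources = sorted(defs.resource_ids) if defs is not None else sorted(
        set().union(*(f.present_resources for f in cohort)) if cohort.n else set()
    )
    inv_rows = [
        {"facility_id": f.facility_id, "resource_id": r,
         "present": int(r in f.present_resources)}
        for f in cohort
        for r in resources
    ]
    pd.DataFrame(
        inv_rows, columns=["facility_id", "resource_id", "present"]
    ).to_csv(inventory_path, index=False, lineterminator="\n")
    attr_rows = [
        {"facility_id": f.facility_id, "country": f.country,
         "ownership": f.ownership, "csec_capable": int(f.csec_capable)}
        for f in cohort
    ]
    pd.DataFrame(attr_rows, columns=list(ATTRIBUTE_COLUMNS)).to_csv(
        attributes_path, index=False, lineterminator="\n"
    )
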