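"""Exception hierarchy for definition, inventory and estimation failures."""

from __future__ import annotations

__all__ = [
    "EmocReadyError",
    "SchemaError",
    "ReferentialIntegrityError",
    "StructuralError",
    "InventoryError",
    "UnknownResourceError",
    "ConflictingRecordError",
    "EstimateError",
    "CountRecoveryError",
    "GeneratorError",
]


class EmocReadyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EmocReadyError):
    """A definition config failed to parse or validate against the schema."""


class ReferentialIntegrityError(EmocReadyError):
    """A requirement references resource tokens that were never declared."""

    def __init__(self, offenders: list[str], where: str = ""):
        self.offenders = sorted(set(offenders))
        loc = f" in {where}" if where else ""
        super().__init__(
            f"undeclared resource token(s){loc}: {', '.join(self.offenders)}"
        )


class StructuralError(EmocReadyError):
    """A cascade or definition set violates a structural invariant."""


class InventoryError(EmocReadyError):
    """An inventory or attributes file is malformed."""


class UnknownResourceError(InventoryError):
    """Inventory mentions resource tokens absent from the definition set."""

    def __init__(self, tokens: list[str]):
        self.tokens = sorted(set(tokens))
        super().__init__(f"unknown resource token(s): {', '.join(self.tokens)}")


class ConflictingRecordError(InventoryError):
    """Duplicate (facility, resource) rows carry contradictory presence flags."""


class EstimateError(EmocReadyError):
    """An aggregate was requested on an empty or degenerate cohort."""


class CountRecoveryError(EmocReadyError):
    """No (or no unique) integer count reproduces a printed percentage."""


class GeneratorError(EmocReadyError):
    """Synthetic-cohort generation was configured inconsistently."""
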