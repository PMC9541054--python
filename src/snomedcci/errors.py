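"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`SnomedCciError` so callers can catch
one base class; subclasses carry the identifiers or column names that caused
the failure, which the CLI surfaces verbatim.
"""

from __future__ import annotations

from collections.abc import Iterable


class SnomedCciError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(SnomedCciError):
    """An input table is missing a required column."""

    def __init__(self, table: str, missing: Iterable[str]):
        self.table = table
        self.missing = sorted(missing)
        super().__init__(
            f"table {table!r} is missing required column(s): {', '.join(self.missing)}"
        )


class IntegrityError(SnomedCciError):
    """An edge table references identifiers absent from the concept table."""

    def __init__(self, table: str, dangling_ids: Iterable[int]):
        self.table = table
        self.dangling_ids = sorted(set(dangling_ids))
        shown = ", ".join(str(i) for i in self.dangling_ids[:20])
        more = "" if len(self.dangling_ids) <= 20 else f" (+{len(self.dangling_ids) - 20} more)"
        super().__init__(
            f"table {table!r} references unknown concept id(s): {shown}{more}"
        )


class ConceptLookupError(SnomedCciError):
    """A query referenced concept ids not present in the store."""

    def __init__(self, ids: Iterable[int]):
        self.ids = sorted(set(ids))
        super().__init__(f"unknown concept id(s): {', '.join(str(i) for i in self.ids)}")


class ContractError(SnomedCciError):
    """A precondition of an operation was violated by the caller."""


class SpecError(SnomedCciError):
    """A synthetic-data specification is internally inconsistent."""


class EstimationError(SnomedCciError):
    """A statistical model could not be estimated (degenerate input or
    non-convergence)."""
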