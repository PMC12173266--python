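"""Exception hierarchy for medmr."""

from __future__ import annotations


class MedMRError(Exception):
    """Base class for all medmr errors."""


class ConfigError(MedMRError):
    """Invalid configuration: missing columns, bad paths, inconsistent options."""


class RowValidationError(MedMRError):
    """One or more input rows violated the per-variant invariants.

    Carries ``rows``: a list of ``(line_number, message)`` pairs, where the
    line number refers to the physical line in the source file (header = 1).
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        preview = "; ".join(f"line {ln}: {msg}" for ln, msg in rows[:5])
        more = "" if len(rows) <= 5 else f" (+{len(rows) - 5} more)"
        super().__init__(f"{len(rows)} invalid row(s): {preview}{more}")


class NoOverlapError(MedMRError):
    """Exposure and outcome tables share no variant identifiers."""


class LDLookupError(MedMRError):
    """The LD source could not provide r2 for a required variant pair."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(f"no LD (r2) available for variant pair ({id_a}, {id_b})")


class InsufficientInstrumentsError(MedMRError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateDesignError(MedMRError):
    """All exposure effects zero (or otherwise rank-deficient design)."""


class DomainError(MedMRError):
    """Argument outside the mathematical domain of a formula."""
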