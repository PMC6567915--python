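"""Exception hierarchy for the workforce-planning simulator.

All model-level failures derive from :class:`HrhSimError` so callers (and the
CLI) can distinguish modelling problems from programming errors.
"""

from __future__ import annotations


class HrhSimError(Exception):
    """Base class for all simulator errors."""


class ParameterNotSpecifiedError(HrhSimError):
    """A stratified table was queried at a tuple with no stored value and no default."""

    def __init__(self, table_name: str, coords: dict):
        self.table_name = table_name or "<unnamed table>"
        self.coords = dict(coords)
        super().__init__(f"parameter not specified: {self.table_name} at {self.coords}")


class DivisionOfWorkError(HrhSimError):
    """Division-of-work shares at a needed stratum do not sum to one."""

    def __init__(self, coords: dict, total: float):
        self.coords = dict(coords)
        self.total = total
        super().__init__(
            f"division-of-work shares sum to {total!r} (expected 1) at {self.coords}"
        )


class ProductivityUndefinedError(HrhSimError):
    """Zero or negative productivity where a profession has allocated workload."""

    def __init__(self, profession: str, service: str, year: int, value: float):
        self.profession, self.service, self.year, self.value = profession, service, year, value
        super().__init__(
            f"productivity undefined for ({profession}, {service}, {year}): {value!r}"
        )


class PipelineNotSeededError(HrhSimError):
    """A graduating cohort's entry year precedes all seeded cohorts and
    steady-state seeding is disabled."""

    def __init__(self, entry_year: int):
        self.entry_year = entry_year
        super().__init__(f"pipeline not seeded for entry year {entry_year}")


class ConfigValidationError(HrhSimError):
    """A configuration failed invariant validation; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"invalid configuration: {lines}{more}")


class ScenarioError(HrhSimError):
    """Base class for scenario construction/application failures."""


class ConflictingOverridesError(ScenarioError):
    """Two overrides target the same parameter, selector and effective year."""


class KeyMismatchError(HrhSimError):
    """Requirement and supply series do not cover the same (profession, year) keys."""

    def __init__(self, missing_in_supply, missing_in_requirements):
        self.missing_in_supply = sorted(missing_in_supply)
        self.missing_in_requirements = sorted(missing_in_requirements)
        super().__init__(
            "requirement/supply key mismatch: "
            f"missing in supply {self.missing_in_supply[:5]}, "
            f"missing in requirements {self.missing_in_requirements[:5]}"
        )


class CalibrationError(HrhSimError):
    """A calibration target cannot be reached with nonnegative parameters."""
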