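"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/domain problems -> 2,
numerical problems -> 3.
"""


class ExposureModelError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(ExposureModelError, ValueError):
    """An input lies outside the physical/model domain (e.g. VP <= 0)."""


class RegistryFormatError(ExposureModelError, ValueError):
    """A registry/substance file failed to parse or misses required keys."""


class UnknownScenarioError(ExposureModelError, KeyError):
    """A scenario code does not resolve in the registry."""

    def __init__(self, code: str, suggestions: list[str]):
        self.code = code
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown scenario code {code!r}{hint}")


class CappedResultError(ExposureModelError, ValueError):
    """Weight-fraction rescaling was attempted on an SVC-capped result.

    The cap breaks linearity in the weight fraction; recompute the scenario
    from scratch instead of rescaling.
    """


class MigrationValidityError(DomainError):
    """The migration-formula validity condition (fraction x time << 1) failed."""


class UnreachableTargetError(DomainError):
    """A target dose cannot be reached (zero migration rate)."""


class NumericalError(ExposureModelError, RuntimeError):
    """An ODE/PDE integration failed; carries solver diagnostics."""
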