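"""Exception hierarchy shared across the package."""


class GenoSchemaError(Exception):
    """Base class for all package-specific errors."""


class UnknownSchemaError(GenoSchemaError, KeyError):
    """A schema id is not present in the registry."""


class UnknownConceptError(GenoSchemaError, KeyError):
    """A concept name is not declared in the schema at hand."""


class InstanceValidationError(GenoSchemaError, ValueError):
    """An instance violates one or more model invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "invalid instance")


class CapabilityError(GenoSchemaError, ValueError):
    """The governing schema cannot represent the requested write.

    Raised when emulating the narrower human- or citrus-specific schemas,
    e.g. genotype frequencies of an indel under CSHG emulation, or an
    external reference under CSCG emulation (which has no bibliography view).
    """


class NoPositionForAssembly(GenoSchemaError, KeyError):
    """An element carries no stored position for the queried assembly."""


class CycleError(GenoSchemaError, ValueError):
    """A containment or composition graph contains a cycle."""


class MissingParticipationError(GenoSchemaError, ValueError):
    """A process inside a pathway has no takes-part record at all."""


class FormatError(GenoSchemaError, ValueError):
    """A malformed external file; carries the offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
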