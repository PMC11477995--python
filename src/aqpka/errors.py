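"""Exception hierarchy shared across the toolkit."""


class AqpkaError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AqpkaError):
    """A species-record file is missing or mistypes a required field."""


class SpeciesValidationError(AqpkaError):
    """A species record violates a hard invariant (e.g. imaginary modes)."""


class GeometryError(AqpkaError):
    """Malformed XYZ input or an unusable geometry."""


class ElementError(GeometryError):
    """Unknown chemical element symbol."""


class ThermoInputError(AqpkaError):
    """A record lacks the data needed for the requested thermochemistry."""


class PairModelError(AqpkaError):
    """A conjugate acid/base pair violates its structural invariants."""


class ProtocolError(AqpkaError):
    """A solvation-energy protocol cannot be applied to a species."""


class BenchmarkError(AqpkaError):
    """Calculated results cannot be matched against the experimental table."""


class FixtureSpecError(AqpkaError):
    """A synthetic-fixture specification is internally inconsistent."""
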