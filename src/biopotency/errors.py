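"""Exception hierarchy."""


class BiopotencyError(Exception):
    """Base class for all package errors."""


class DomainError(BiopotencyError, ValueError):
    """A numeric input lies outside its mathematical domain (e.g. IC50 <= 0)."""


class UnitError(BiopotencyError, ValueError):
    """An unrecognized or unsupported unit token."""


class SchemaError(BiopotencyError, ValueError):
    """A file does not conform to the expected tabular/JSON schema."""


class TreeStructureError(BiopotencyError, ValueError):
    """A purification tree violates structural constraints (cycles, dangling parents, multiple roots)."""


class NotComputableError(BiopotencyError, ValueError):
    """A requested quantity cannot be computed from the data present."""
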