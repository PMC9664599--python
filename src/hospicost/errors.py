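"""Exception hierarchy for the costing pipeline."""


class HospicostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HospicostError):
    """A configuration value violates its invariant; message names the field."""


class DomainError(HospicostError):
    """An operation received input outside its mathematical domain."""


class AllocationError(HospicostError):
    """Shared-cost apportionment could not proceed (e.g. all-zero weights)."""


class SchemaError(HospicostError):
    """An input table does not match the documented schema."""


class IntegrityError(HospicostError):
    """Referential integrity between tables is broken (orphan keys)."""
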