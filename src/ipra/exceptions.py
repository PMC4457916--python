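"""Exception hierarchy for the IPRA package."""


class IpraError(Exception):
    """Base class for all package errors."""


class ParameterError(IpraError, ValueError):
    """An argument or configuration value is outside its valid domain."""


class DataError(IpraError):
    """Input data violate a structural invariant."""


class SchemaError(DataError):
    """A table is missing a required column or contains an unparsable cell."""


class LinkageError(DataError):
    """A product-link row refers to an unknown basic product."""


class FixtureIntegrityError(DataError):
    """A packaged fixture failed its checksum."""


class DegenerateDataError(DataError):
    """Data carry no information for the requested fit (e.g. no positive exposures)."""


class ModelError(IpraError):
    """Unknown model name or invalid model state."""


class FitError(ModelError):
    """An optimiser failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class Ed50UndefinedError(ModelError):
    """The fitted curve has no positive dose with response midway to one."""


class SelectionError(ModelError):
    """Model selection was asked to choose among zero converged fits."""


class SolverError(IpraError):
    """A root-finding problem has no root in the searched bracket."""


class DesignError(IpraError):
    """A factorial design table is rank-deficient or contains duplicates."""


class RunError(IpraError):
    """Too many Monte Carlo iterations failed for the run to be trusted."""
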