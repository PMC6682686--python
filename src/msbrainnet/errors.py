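"""Exception hierarchy shared across the package."""


class MSBrainNetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MSBrainNetError):
    """A table is missing a mandatory column or has the wrong layout."""


class ValidationError(MSBrainNetError):
    """A value violates a documented domain invariant."""


class SpecError(MSBrainNetError):
    """A synthetic-scenario specification is internally inconsistent."""


class UndefinedModularityError(MSBrainNetError):
    """Modularity is requested on a graph with no edge mass (2m = 0)."""
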