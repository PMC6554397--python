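"""Exception hierarchy shared across the package."""


class ColonyFlowError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(ColonyFlowError, ValueError):
    """A channel dimension is nonpositive or otherwise unphysical."""


class InvalidParameterError(ColonyFlowError, ValueError):
    """A physical or numerical parameter is outside its valid range."""


class RegimeError(ColonyFlowError, ValueError):
    """A closed-form expression was requested outside its regime of validity."""
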