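"""Exception hierarchy."""


class HemothermError(Exception):
    """Base class for all package errors."""


class LoadError(HemothermError):
    """A packaged or user parameter file is missing or unreadable."""


class ValidationError(HemothermError):
    """A parameter value violates its documented invariant."""


class TopologyError(HemothermError):
    """The arterial tree or thermal network connectivity is inconsistent."""


class GeometryError(HemothermError):
    """Simplified geometry is degenerate (e.g. r_out <= r_in)."""


class NumericsError(HemothermError):
    """A solver failed to converge or produced an unstable state."""


class CouplingError(HemothermError):
    """A 1-D/0-D or CV/TNW exchange value is missing or unmapped."""
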