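"""Exception hierarchy shared across the package."""


class BridgescopeError(Exception):
    """Base class for all package errors."""


class ParseError(BridgescopeError):
    """A structure or table file could not be parsed."""


class TopologyError(BridgescopeError):
    """Frames of an ensemble disagree on the atom set."""


class SelectionError(BridgescopeError):
    """An atom selection matched nothing."""


class StructuralCompletenessError(BridgescopeError):
    """A residue is missing an atom required by an analysis."""


class SuperpositionError(BridgescopeError):
    """Anchor atoms are too few or degenerate for a rigid fit."""


class FitError(BridgescopeError):
    """A nonlinear fit failed to converge."""
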