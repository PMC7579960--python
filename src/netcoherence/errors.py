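"""Exception hierarchy for the coherence pipeline."""


class NetCoherenceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetCoherenceError):
    """A file does not conform to the expected dialect (missing columns,
    malformed record); carries file/line context where available."""


class DegenerateSlopeError(NetCoherenceError):
    """A through-origin slope is undefined: every internal degree is zero."""


class PanelError(NetCoherenceError):
    """A reference panel cannot be built or is degenerate (beta_min == beta_max)."""


class AssemblyError(NetCoherenceError):
    """Random-network assembly exceeded its draw cap (pathologically sparse
    interactome for the requested size)."""


class ModularityError(NetCoherenceError):
    """Modularity is undefined: the induced subnetwork has no edges."""
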