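"""Exception hierarchy shared across the package."""


class GdrepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GdrepError):
    """A chain table does not conform to the requested dialect."""


class LocusError(GdrepError):
    """A record carries a V call from an unsupported locus."""


class ConsistencyError(GdrepError):
    """Internal data contradicts itself (e.g. nt variant vs aa sequence)."""


class ConfigError(GdrepError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(GdrepError):
    """A pipeline stage failed; message names the stage and the cause."""
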