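"""Exception hierarchy for mirpanel.

All errors derive from :class:`MirpanelError` so callers (and the CLI)
can catch pipeline failures uniformly while tests can assert on the
specific failure mode.
"""


class MirpanelError(Exception):
    """Base class for all mirpanel errors."""


class MalformedIdentifierError(MirpanelError, ValueError):
    """Raised for empty or unparseable miRNA/gene identifiers."""


class SchemaError(MirpanelError, ValueError):
    """A mapped column is missing from an input table."""


class RegistryError(MirpanelError, ValueError):
    """A prediction file is attributed to a tool not in the registry."""


class ConfigurationError(MirpanelError, ValueError):
    """Invalid run configuration (empty panel, unknown level, ...)."""


class DomainError(MirpanelError, ValueError):
    """A score or count is outside its mathematically valid range."""


class MalformedScoreError(MirpanelError, ValueError):
    """A PPI combined score is outside the accepted raw range."""


class NormalizationError(MirpanelError, ValueError):
    """Reference assay / control group missing or unusable."""


class InsufficientDataError(MirpanelError, ValueError):
    """Too few observations for the requested statistic."""
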