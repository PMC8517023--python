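"""Exception hierarchy shared across the package."""


class Kv7Pip2Error(Exception):
    """Base class for all package-specific errors."""


class SelectionError(Kv7Pip2Error):
    """A selection is empty, overlapping, or otherwise unusable."""


class GeometryError(Kv7Pip2Error):
    """Degenerate geometry (too few points, collinear/spherical clouds)."""


class ConfigurationError(Kv7Pip2Error):
    """Invalid generator or pipeline configuration."""


class PlanError(Kv7Pip2Error):
    """Inconsistent planted-event plan (overlapping dwells at one site, ...)."""


class SchemaError(Kv7Pip2Error):
    """Invalid headgroup moiety schema or unknown moiety class."""


class FormatError(Kv7Pip2Error):
    """Malformed input file (e.g. model atom-count mismatch in a PDB)."""
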