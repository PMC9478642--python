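"""Exception hierarchy shared across the package."""


class FilbundleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FilbundleError):
    """A file could not be parsed, or violates a format invariant."""


class ConfigError(FilbundleError):
    """Invalid configuration value (e.g. min > max in a sampling range)."""


class DegenerateGeometryError(FilbundleError):
    """Geometric input is degenerate (too few points, collinear sets, ...)."""


class SelectionError(FilbundleError):
    """An atom/residue selection matched nothing in a model."""


class BoxSizeError(FilbundleError):
    """A rendering box is too small to contain the requested object."""
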