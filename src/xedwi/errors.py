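"""Exception hierarchy.

All package errors derive from :class:`XedwiError` so callers (and the CLI,
which maps them to exit code 2) can catch them uniformly.
"""


class XedwiError(Exception):
    """Base class for all xedwi errors."""


class FormatError(XedwiError, ValueError):
    """Malformed or inconsistent input data (files, arrays, b-value lists)."""


class ParameterError(XedwiError, ValueError):
    """A parameter outside its physically or statistically valid range."""


class GeometryError(XedwiError, ValueError):
    """Invalid phantom or mask geometry (e.g. overlapping lungs)."""
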