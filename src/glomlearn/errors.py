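"""Exception hierarchy.

All pipeline failures derive from :class:`GlomlearnError` so callers (and the
CLI) can catch one base class. The three leaves mirror the kinds of contract
a stage can break: a bad parameter, bad data, or degenerate geometry.
"""


class GlomlearnError(Exception):
    """Base class for all errors raised by glomlearn."""


class ParameterError(GlomlearnError, ValueError):
    """A configuration or function parameter violates its contract."""


class DataError(GlomlearnError, ValueError):
    """Input data violate an invariant (e.g. non-positive baseline F0)."""


class GeometryError(GlomlearnError, ValueError):
    """A polygon, frustum stack or grid is degenerate or inconsistent."""
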