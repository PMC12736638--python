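"""Exception hierarchy.

Three branches so the CLI can map failures to distinct exit codes:
configuration problems, malformed or inconsistent input data, and
computation-level errors (degenerate inputs, domain violations).
"""


class DmwiError(Exception):
    """Base class for all package errors."""


class ConfigError(DmwiError):
    """Invalid run configuration (schema violation, unknown key, bad value)."""


class DataError(DmwiError):
    """Malformed or mutually inconsistent input data (files, grids, shapes)."""


class ComputationError(DmwiError):
    """Degenerate or out-of-domain numerical input."""
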