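"""Exception hierarchy shared across the package.

Domain errors on otherwise-valid values (inconsistent counts, out-of-range
thresholds) raise plain :class:`ValueError`; these classes cover failures
tied to external inputs.
"""


class ToxFocusError(Exception):
    """Base class for package-specific errors."""


class FormatError(ToxFocusError):
    """An input file violates its format contract (missing column, short line)."""


class ConfigError(ToxFocusError):
    """A configuration document is invalid (unknown key, wrong type, infeasible value)."""
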