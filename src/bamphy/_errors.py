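"""Exception types shared across the package."""


class BamphyError(Exception):
    """Base class for package errors."""


class ArgumentError(BamphyError, ValueError):
    """A caller supplied an argument outside the function's contract."""


class DataError(BamphyError, ValueError):
    """Input data is malformed or inconsistent (bad alphabet, bad coordinates,
    mismatched leaf sets, ...)."""
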