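"""Exception types shared across the package."""


class TetrabinError(Exception):
    """Base class for package-specific failures."""


class IndexFormatError(TetrabinError):
    """A persisted fragment index is corrupt, missing files, or has an
    unrecognized format/version string."""


class ConfigMismatchError(TetrabinError):
    """An index was built under settings incompatible with the requested
    run (e.g. strand-symmetric vectors queried in forward mode)."""


class InvariantError(TetrabinError):
    """An internal consistency check failed; indicates a bug, not bad input."""
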