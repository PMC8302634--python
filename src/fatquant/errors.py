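"""Exception hierarchy.

Three failure families are kept apart so batch drivers can react differently:
unreadable/garbled files (:class:`ImageIOError`), structurally invalid data
such as a missing label or an empty ROI (:class:`DataError`), and caller
mistakes such as contradictory options (:class:`UsageError`).
"""


class FatquantError(Exception):
    """Base class for all package errors."""


class ImageIOError(FatquantError):
    """A file could not be read or written in the requested format."""


class DataError(FatquantError):
    """Input parsed but is unusable (empty mask, missing label, shape mismatch)."""


class UsageError(FatquantError):
    """The caller supplied contradictory or out-of-range options."""
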