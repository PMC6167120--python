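"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: validation errors exit 2, I/O errors
exit 3, capacity errors exit 4.
"""


class ClampwiseError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ValidationError(ClampwiseError):
    """Invalid user input: bad symbols, bad coordinates, bad probabilities."""

    exit_code = 2


class InputError(ClampwiseError):
    """Unreadable or malformed input files."""

    exit_code = 3


class CapacityError(ClampwiseError):
    """A computation exceeds a documented capacity cap (e.g. degeneracy)."""

    exit_code = 4
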