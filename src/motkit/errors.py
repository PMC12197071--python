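"""Exception hierarchy for the toolkit.

Precondition violations on plain numeric arguments raise ``ValueError``;
wire-format and file-format problems get dedicated classes so callers can
distinguish "bad input" from "corrupted stream".
"""


class MotkitError(Exception):
    """Base class for toolkit-specific errors."""


class MalformedPacketError(MotkitError):
    """A node->hub packet could not be decoded (wrong length, bad fields)."""


class MalformedFrameError(MotkitError):
    """A hub->host serial frame is internally inconsistent."""


class FramingError(MotkitError):
    """The end-of-frame marker is missing from a serial byte stream."""


class DuplicatePacketError(MotkitError):
    """A packet repeated the previous counter value (gap of -1)."""


class ReorderingError(MotkitError):
    """A counter gap exceeding 2**31, treated as out-of-order delivery."""


class SchemaError(MotkitError):
    """A recording's JSON sidecar is missing a required metadata field."""


class CorruptFileError(MotkitError):
    """A recording's binary stream has an impossible length or code range."""
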