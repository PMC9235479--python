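"""Exception types shared across the package."""


class MinidexError(Exception):
    """Base class for all package-specific errors."""


class InvalidBaseError(MinidexError, ValueError):
    """A character outside {A,C,G,T} (case-insensitive) in a cover string.

    ``position`` is the 0-based offset of the offending character within the
    string that was being encoded.
    """

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"invalid DNA base {char!r} at position {position}")


class AlienWindowError(MinidexError, IndexError):
    """A k-mer window crosses a string boundary in the concatenated storage."""


class ShortStringError(MinidexError, ValueError):
    """A cover string shorter than k was supplied."""


class MonotonicityError(MinidexError, ValueError):
    """A sequence handed to the Elias-Fano encoder is not non-decreasing."""


class UniverseError(MinidexError, ValueError):
    """A value exceeds the declared universe of an Elias-Fano sequence."""


class DuplicateKeyError(MinidexError, ValueError):
    """Duplicate keys handed to a minimal perfect hash construction."""


class IntegrityError(MinidexError, ValueError):
    """The input collection violates the no-duplicate-k-mer contract."""


class IndexFormatError(MinidexError, ValueError):
    """A serialized index file is corrupt or has an incompatible version."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class ConfigMismatchError(MinidexError, ValueError):
    """A query was issued with parameters incompatible with the index."""


class GenerationError(MinidexError, RuntimeError):
    """Synthetic-cover generation could not satisfy its constraints."""
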