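"""Exception hierarchy for cdbgzip.

Parse errors (bad user input) and corrupt-archive errors are kept distinct so
the CLI can map them onto separate exit codes.
"""


class CdbgzipError(Exception):
    """Base class for all cdbgzip errors."""


class InvalidAlphabetError(CdbgzipError, ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class ParseError(CdbgzipError, ValueError):
    """Malformed user input (FASTA, k-mer list, bad parameter)."""


class ConsistencyError(CdbgzipError, ValueError):
    """Internal pipeline stages disagree (e.g. a colored k-mer missing
    from the union ordering)."""


class CorruptArchiveError(CdbgzipError, ValueError):
    """An archive or bit stream cannot be decoded losslessly."""
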