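"""Exception hierarchy shared across the package."""


class AtlasError(Exception):
    """Base class for all tissueatlas errors."""


class FormatError(AtlasError):
    """A file or table violates the expected format (duplicates, bad cells)."""


class ValidationError(AtlasError):
    """A value violates a domain invariant (negative abundance, bad residue)."""


class MappingError(AtlasError):
    """An identifier cannot be resolved against its companion table."""


class UndefinedStatisticError(AtlasError):
    """A requested statistic is undefined for the given input (e.g. 0/0)."""
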