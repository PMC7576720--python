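"""Exception types shared across the package."""


class DktaxError(Exception):
    """Base class for all package-specific errors."""


class AmbiguousBaseError(DktaxError):
    """A k-mer window contains a base outside {A,C,G,T} (e.g. N)."""


class FormatError(DktaxError):
    """A file does not conform to the expected on-disk format."""


class CycleError(DktaxError):
    """A taxonomy parent chain does not terminate at the root."""


class UnknownTaxidError(DktaxError):
    """A taxonomy ID is not present in the loaded tree."""


class EmptyInputError(DktaxError):
    """An input that must yield at least one record/window yielded none."""


class ShortReadError(DktaxError):
    """A query read is shorter than the k-mer length."""
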