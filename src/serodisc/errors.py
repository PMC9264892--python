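"""Exception types shared across the pipeline."""


class SerodiscError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SerodiscError, ValueError):
    """A file or structure does not match the expected layout."""


class ParseError(SerodiscError, ValueError):
    """A value inside an otherwise well-formed file could not be parsed."""


class IntegrityError(SerodiscError, ValueError):
    """Internally inconsistent data (duplicate replicates, bad point counts)."""


class RangeError(SerodiscError, ValueError):
    """A requested spectral range or factor does not fit the data."""


class DegenerateDataError(SerodiscError, ValueError):
    """Data that makes an operation mathematically undefined (zero-variance
    spectrum, single-class labels, vanishing EMSC scale factor)."""


class StratificationError(SerodiscError, ValueError):
    """A class has too few patients to be split into train and test."""
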