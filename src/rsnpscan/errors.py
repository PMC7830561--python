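"""Exception hierarchy shared across the package."""


class RsnpScanError(Exception):
    """Base class for all package errors."""


class FormatError(RsnpScanError):
    """A file does not conform to its declared format."""


class DataIntegrityError(RsnpScanError):
    """Inputs are well-formed but mutually inconsistent (e.g. VCF REF
    disagreeing with the genome base at that position)."""


class ParameterError(RsnpScanError):
    """An argument is outside its valid range."""
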