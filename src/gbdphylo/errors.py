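"""Exception hierarchy shared across the package."""


class GBDPError(Exception):
    """Base class for all package errors."""


class FormatError(GBDPError):
    """Malformed input file (wrong column count, bad FASTA, broken Newick...)."""


class ValidationError(GBDPError):
    """Well-formed input violating a domain invariant (bad residue, asymmetry...)."""


class UsageError(GBDPError):
    """API misuse: mismatched sequence types, unknown leaves, duplicate ids..."""


class ParameterError(GBDPError):
    """Unusable numerical parameters (e.g. non-negative expected alignment score)."""
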