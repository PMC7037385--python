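"""Exception hierarchy shared across the package."""


class AzoleQsarError(Exception):
    """Base class for all package errors."""


class SmilesParseError(AzoleQsarError):
    """A SMILES string could not be parsed."""


class MixtureError(AzoleQsarError):
    """Input structure is disconnected (a mixture or salt pair)."""


class SmartsPatternError(AzoleQsarError):
    """A SMARTS pattern could not be compiled."""


class UnsupportedElementError(AzoleQsarError):
    """Element outside the supported set (C, N, O, S, P, halogens)."""


class UnitsError(AzoleQsarError):
    """Electronic descriptor unit/method tags do not match expectations."""


class DegenerateGapError(AzoleQsarError):
    """HOMO and LUMO energies coincide; hardness is zero."""


class NoPositiveCenterError(AzoleQsarError):
    """No non-hydrogen atom carries a positive partial charge."""


class MissingDescriptorError(AzoleQsarError):
    """A model term has no matching entry in the descriptor vector."""


class CollinearityError(AzoleQsarError):
    """Design matrix is rank deficient."""
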