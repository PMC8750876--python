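"""Exception hierarchy for cytomr.

Every error raised by the library derives from :class:`CytomrError` so callers
(the pipeline in particular) can record per-pair failures without aborting a run.
"""


class CytomrError(Exception):
    """Base class for all cytomr errors."""


class ConfigError(CytomrError):
    """A configuration problem: missing column mapping, bad threshold, etc."""


class FormatError(CytomrError):
    """An input file violates its format contract (non-square LD, bad diagonal...)."""


class EmptyInputError(CytomrError):
    """An input table contained no usable rows."""


class EmptyOverlapError(CytomrError):
    """Two summary-statistic sets share no variants."""


class InsufficientOverlapError(CytomrError):
    """Fewer shared variants than an operation requires."""


class DomainError(CytomrError):
    """A numeric argument is outside the mathematical domain of an operation."""


class MissingLDError(CytomrError):
    """A variant required by clumping or LD-aware estimation is absent from the LD matrix."""


class DegenerateInstrumentError(CytomrError):
    """An instrument with zero exposure effect cannot produce a ratio estimate."""


class InsufficientInstrumentsError(CytomrError):
    """Fewer instruments than an estimator requires."""


class CollinearityError(CytomrError):
    """A design matrix is rank deficient (near-collinear instruments or exposures)."""
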