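"""Exception hierarchy shared across the package.

All errors raised deliberately by specfret derive from :class:`SpecFretError`
so callers (and the CLI) can separate input problems from computation
problems.
"""


class SpecFretError(Exception):
    """Base class for all specfret errors."""


class FormatError(SpecFretError):
    """Malformed input file (bad columns, non-monotone abscissa, too short)."""


class GridError(SpecFretError):
    """Pointwise operation attempted on mismatched abscissa grids."""


class RangeError(SpecFretError):
    """Requested grid or interval lies outside the data range."""


class DegenerateSpectrumError(SpecFretError):
    """Normalizer or reference signal is zero/negative where it must be positive."""


class DivisionError(SpecFretError):
    """Denominator spectrum is non-positive inside the analysis window."""


class PairingError(SpecFretError):
    """Replicate lists that must be paired have mismatched lengths."""


class StatisticsError(SpecFretError):
    """Not enough (or degenerate) data for the requested statistic."""


class SiteError(SpecFretError):
    """Requested residue site absent from the structure."""


class EmptyEnsembleError(SpecFretError):
    """Every sampled conformer clashed; loosen the clash cutoff."""


class DegenerateDistanceError(SpecFretError):
    """Zero donor-acceptor distance encountered."""


class PrecisionError(SpecFretError):
    """Monte-Carlo sample size too small for a non-enumerable state space."""


class FitError(SpecFretError):
    """Nonlinear fit failed to converge."""


class AnnotationError(SpecFretError):
    """Required trace event annotation is missing."""


class DegenerateTraceError(SpecFretError):
    """Flux trace has no usable dynamic range (f_max <= f_min)."""
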