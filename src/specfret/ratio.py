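"""Ratio-based spectral FRET quantification.

The analysis separates the acceptor emission obtained under donor excitation
into a direct-excitation part and a transfer part:

1. the donor-only control spectrum is scaled so its donor-band area matches
   the sample's (``scale_donor_reference``);
2. subtracting the scaled control leaves the extracted acceptor spectrum
   (``extract_acceptor_spectrum``);
3. dividing by the directly excited acceptor spectrum gives a per-wavelength
   ratio trace whose mean over the acceptor band is ``ratio_a``
   (``ratio_a_trace``);
4. the same ratio measured on the free acceptor alone gives ``ratio_a0``,
   and ``ratio_a - ratio_a0`` is proportional to the FRET efficiency.

A flat ratio trace is itself a quality check — any wavelength dependence
signals contaminating fluorescence or detector non-linearity — so the
coefficient of variation over the averaging window is reported as
``flatness``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSpectrumError,
    DivisionError,
    PairingError,
    StatisticsError,
)
from .spectra import Spectrum, common_grid, interpolate_to_grid

__all__ = [
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "KNOWN_CONDITIONS",
    "SpectralFretInput",
    "RatioAResult",
    "ConditionComparison",
    "scale_donor_reference",
    "extract_acceptor_spectrum",
    "ratio_a_trace",
    "ratio_a0",
    "relative_fret",
    "analyze",
    "compare_conditions",
]

#: Default donor-band window (nm) used to scale the donor-only reference.
DONOR_WINDOW = (300.0, 360.0)
#: Default acceptor-band averaging window (nm), endpoints inclusive.
ACCEPTOR_WINDOW = (410.0, 480.0)
#: Recognized condition labels; anything else triggers a warning only.
KNOWN_CONDITIONS = frozenset({"apo", "zinc", "zinc_edta"})


@dataclass(frozen=True)
class SpectralFretInput:
    """One replicate's trio of emission spectra.

    ``f280``: sample excited in the donor band; ``f370``: sample excited in
    the acceptor band only; ``f280_notag``: donor-only control excited in
    the donor band.
    """

    f280: Spectrum
    f370: Spectrum
    f280_notag: Spectrum
    construct_id: str = ""
    condition: str = "apo"
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("f280", "f370", "f280_notag"):
            s: Spectrum = getattr(self, name)
            if s.kind.value != "emission":
                raise ValueError(f"{name} must be an emission spectrum")
        if self.condition not in KNOWN_CONDITIONS:
            warnings.warn(
                f"condition {self.condition!r} not in {sorted(KNOWN_CONDITIONS)}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RatioAResult:
    """Per-wavelength acceptor ratio trace and its scalar summaries."""

    wavelength: np.ndarray
    ratio_trace: np.ndarray
    ratio_a: float
    flatness: float
    averaging_window: tuple[float, float] = ACCEPTOR_WINDOW
    ratio_a0: float = float("nan")
    construct_id: str = ""
    condition: str = "apo"
    replicate: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ratio_trace)):
            raise DivisionError("non-finite values in ratio trace")

    @property
    def relative_fret(self) -> float:
        """``ratio_a - ratio_a0``; NaN until ratio_a0 is attached."""
        return self.ratio_a - self.ratio_a0

    def with_ratio_a0(self, ratio_a0: float) -> "RatioAResult":
        from dataclasses import replace

        return replace(self, ratio_a0=float(ratio_a0))


@dataclass(frozen=True)
class ConditionComparison:
    """Paired per-replicate comparison of one condition against apo."""

    construct_id: str
    deltas: np.ndarray
    mean_delta: float
    p_value: float
    reversibility: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatisticsError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def scale_donor_reference(
    f280: Spectrum,
    f280_notag: Spectrum,
    donor_window: tuple[float, float] = DONOR_WINDOW,
) -> Spectrum:
    """Scale the donor-only control to the sample's donor-band area.

    Returns ``f280_notag`` multiplied by the scalar that equates its
    trapezoidal integral over ``donor_window`` with that of ``f280``.
    Area matching is used rather than peak matching because it is less
    sensitive to noise at a single wavelength.
    """
    ref_area = f280_notag.integral(donor_window)
    sample_area = f280.integral(donor_window)
    if ref_area <= 0:
        raise DegenerateSpectrumError(
            f"donor reference area {ref_area!r} over {donor_window} not positive"
        )
    scale = sample_area / ref_area
    return f280_notag.with_intensity(f280_notag.intensity * scale)


def extract_acceptor_spectrum(f280: Spectrum, scaled_notag: Spectrum) -> Spectrum:
    """Pointwise ``f280 - scaled_notag`` on the common grid.

    The residual contains the acceptor emission only: its direct-excitation
    component plus the transfer component.
    """
    g = common_grid(f280, scaled_notag)
    a = interpolate_to_grid(f280, g)
    b = interpolate_to_grid(scaled_notag, g)
    return a.with_intensity(a.intensity - b.intensity)


def _windowed_ratio(
    num: Spectrum, den: Spectrum, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    g = common_grid(num, den, interval=window)
    n = interpolate_to_grid(num, g).intensity
    d = interpolate_to_grid(den, g).intensity
    if np.any(d <= 0):
        raise DivisionError(
            f"denominator spectrum non-positive inside window {window}"
        )
    return g, n / d


def ratio_a_trace(
    extracted: Spectrum,
    f370: Spectrum,
    window: tuple[float, float] = ACCEPTOR_WINDOW,
    **ids,
) -> RatioAResult:
    """Ratio trace (extracted acceptor / directly excited acceptor).

    ``ratio_a`` is the unweighted mean of the trace over ``window``
    (endpoints inclusive); ``flatness`` is its coefficient of variation.
    """
    g, trace = _windowed_ratio(extracted, f370, window)
    mean = float(np.mean(trace))
    flat = float(np.std(trace) / abs(mean)) if mean != 0 else float("inf")
    return RatioAResult(
        wavelength=g, ratio_trace=trace, ratio_a=mean, flatness=flat,
        averaging_window=(float(window[0]), float(window[1])), **ids,
    )


def ratio_a0(
    free_acceptor_f280: Spectrum,
    free_acceptor_f370: Spectrum,
    window: tuple[float, float] = ACCEPTOR_WINDOW,
) -> float:
    """Direct-excitation ratio measured on the free acceptor alone."""
    _, trace = _windowed_ratio(free_acceptor_f280, free_acceptor_f370, window)
    return float(np.mean(trace))


def relative_fret(ratio_a: float, ratio_a0: float) -> float:
    """Transfer component of the ratio; proportional to FRET efficiency."""
    return ratio_a - ratio_a0


def analyze(
    inp: SpectralFretInput,
    free_acceptor_f280: Spectrum,
    free_acceptor_f370: Spectrum,
    donor_window: tuple[float, float] = DONOR_WINDOW,
    window: tuple[float, float] = ACCEPTOR_WINDOW,
) -> RatioAResult:
    """Full pipeline for one replicate, ratio_a0 attached."""
    scaled = scale_donor_reference(inp.f280, inp.f280_notag, donor_window)
    extracted = extract_acceptor_spectrum(inp.f280, scaled)
    result = ratio_a_trace(
        extracted, inp.f370, window,
        construct_id=inp.construct_id, condition=inp.condition,
        replicate=inp.replicate,
    )
    a0 = ratio_a0(free_acceptor_f280, free_acceptor_f370, window)
    return result.with_ratio_a0(a0)


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def _relative_frets(results: list[RatioAResult] | np.ndarray) -> np.ndarray:
    if len(results) and isinstance(results[0], RatioAResult):
        return np.array([r.relative_fret for r in results], dtype=float)
    return np.asarray(results, dtype=float)


def compare_conditions(
    apo,
    treated,
    reversal=None,
    construct_id: str = "",
) -> ConditionComparison:
    """Paired comparison of relative-FRET replicates against apo.

    ``deltas`` are per-replicate ``treated - apo`` differences; the p-value
    comes from a two-sided paired t-test (p = 1 reported when all deltas are
    identical and the t statistic is undefined).  When EDTA-reversal
    replicates are supplied, ``reversibility`` is the fraction of the
    treatment-induced shift undone:
    ``1 - |mean(reversal) - mean(apo)| / |mean(treated) - mean(apo)|``.
    """
    a = _relative_frets(apo)
    t = _relative_frets(treated)
    if a.size != t.size:
        raise PairingError(f"unpaired replicate counts: {a.size} vs {t.size}")
    if a.size < 2:
        raise StatisticsError("need at least 2 paired replicates")
    deltas = t - a
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        # undefined t statistic: identical pairs report p = 1, an exactly
        # constant nonzero shift is unambiguous evidence (p = 0)
        p = 1.0 if np.all(deltas == 0.0) else 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_rel(t, a).pvalue)
        if not np.isfinite(p):
            p = 1.0
    rev = float("nan")
    if reversal is not None:
        r = _relative_frets(reversal)
        shift = abs(float(np.mean(t) - np.mean(a)))
        if shift == 0:
            raise StatisticsError("reversibility undefined: no treatment shift")
        rev = 1.0 - abs(float(np.mean(r) - np.mean(a))) / shift
    return ConditionComparison(
        construct_id=construct_id,
        deltas=deltas,
        mean_delta=float(np.mean(deltas)),
        p_value=p,
        reversibility=rev,
    )
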