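"""TCSPC decay fitting with instrument-response reconvolution.

The model for a photon-arrival histogram is

    model(t) = background + [irf (*) sum_k A_k exp(-t / tau_k)](t - shift)

where ``(*)`` is discrete convolution on the uniform bin grid and the IRF
is the measured instrument response (a delta function when none is given).
Parameters are estimated by weighted least squares with Poisson weights
(variance = max(counts, 1)), which is adequate at the photon counts used
here; a Poisson maximum-likelihood objective is available as an option.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, FormatError

__all__ = ["DecayHistogram", "DecayFit", "read_decay", "fit_decay", "mean_lifetime"]


@dataclass(frozen=True)
class DecayHistogram:
    """Photon-count histogram on uniform time bins, optional IRF alongside."""

    time_bins: np.ndarray  # bin centers, ns, uniform spacing
    counts: np.ndarray
    irf_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_bins, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "time_bins", t)
        object.__setattr__(self, "counts", c)
        if t.size != c.size or t.size < 4:
            raise FormatError("time_bins and counts must align, length >= 4")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise FormatError("time bins must be uniform and increasing")
        if np.any(c < 0):
            raise FormatError("negative counts")
        if self.irf_counts is not None:
            irf = np.asarray(self.irf_counts, dtype=float)
            if irf.size != t.size:
                raise FormatError("IRF must share the decay's bins")
            if np.any(irf < 0) or irf.sum() <= 0:
                raise FormatError("IRF counts must be nonnegative with mass")
            object.__setattr__(self, "irf_counts", irf)

    @property
    def bin_width(self) -> float:
        return float(self.time_bins[1] - self.time_bins[0])


@dataclass(frozen=True)
class DecayFit:
    """Reconvolution fit result; lifetimes sorted ascending."""

    lifetimes: np.ndarray  # ns
    amplitudes: np.ndarray  # fractional, sum to 1
    shift: float  # ns
    background: float  # counts per bin
    goodness: float  # reduced chi-square
    n_photons: float

    @property
    def mean_lifetime(self) -> float:
        return float(np.dot(self.amplitudes, self.lifetimes))


def read_decay(path: str | os.PathLike[str],
               irf_path: str | os.PathLike[str] | None = None) -> DecayHistogram:
    """Load decay (and optionally IRF) from two-column time/counts text."""
    from .spectra import _parse_two_columns  # same dialect

    with open(os.fspath(path), encoding="utf-8") as fh:
        t, c = _parse_two_columns(fh.read(), os.fspath(path))
    irf = None
    if irf_path is not None:
        with open(os.fspath(irf_path), encoding="utf-8") as fh:
            t2, irf = _parse_two_columns(fh.read(), os.fspath(irf_path))
        if t2.size != t.size or not np.allclose(t2, t):
            raise FormatError("IRF time axis differs from decay time axis")
    return DecayHistogram(time_bins=t, counts=c, irf_counts=irf)


def _model_counts(time_rel: np.ndarray, irf_norm: np.ndarray | None,
                  amps: np.ndarray, taus: np.ndarray, shift: float,
                  background: float, dt: float) -> np.ndarray:
    decay = np.zeros_like(time_rel)
    for a, tau in zip(amps, taus):
        decay += a * np.exp(-np.clip(time_rel, 0, None) / tau)
    decay[time_rel < 0] = 0.0
    if irf_norm is None:
        model = decay
        if abs(shift) > 1e-12:
            model = np.interp(time_rel - shift, time_rel, decay,
                              left=0.0, right=0.0)
        return model + background
    # shift the IRF on its own grid, then convolve
    idx = np.arange(irf_norm.size, dtype=float)
    irf_shifted = np.interp(idx - shift / dt, idx, irf_norm,
                            left=0.0, right=0.0)
    model = np.convolve(irf_shifted, decay)[: time_rel.size]
    return model + background


def fit_decay(
    decay: DecayHistogram,
    n_components: int = 1,
    init: dict | None = None,
    fit_shift: bool = True,
    objective: str = "wls",
) -> DecayFit:
    """Fit an ``n_components`` multi-exponential by IRF reconvolution.

    ``init`` may provide ``lifetimes`` (ns) and ``background`` guesses.
    With ``objective="mle"`` the Poisson deviance residuals are minimised
    instead of Poisson-weighted least squares.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    needed = 10 * n_components * 3
    if int(np.count_nonzero(decay.counts)) < needed:
        raise FitError(
            f"too few populated bins for {n_components} components "
            f"(need >= {needed})"
        )
    t = decay.time_bins
    counts = decay.counts
    dt = decay.bin_width
    time_rel = t - t[0]
    irf_norm = None
    if decay.irf_counts is not None:
        irf_norm = decay.irf_counts / decay.irf_counts.sum()

    total = float(counts.sum())
    span = float(time_rel[-1])
    guesses = (init or {}).get(
        "lifetimes",
        [span / 5.0 * (k + 1) / n_components for k in range(n_components)],
    )
    bg0 = float((init or {}).get("background", max(counts.min(), 0.0)))
    # params: log-amplitudes (counts scale), log-lifetimes, shift, background
    p0 = np.concatenate([
        np.log(np.full(n_components, total / n_components)),
        np.log(np.asarray(guesses, dtype=float)),
        [0.0, bg0],
    ])

    sigma = np.sqrt(np.maximum(counts, 1.0))

    def unpack(p):
        amps = np.exp(p[:n_components])
        taus = np.exp(p[n_components:2 * n_components])
        shift = p[-2] if fit_shift else 0.0
        background = abs(p[-1])
        return amps, taus, shift, background

    def residuals(p):
        amps, taus, shift, background = unpack(p)
        m = _model_counts(time_rel, irf_norm, amps, taus, shift, background, dt)
        if objective == "mle":
            # signed square root of the Poisson deviance contribution
            m = np.clip(m, 1e-12, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(counts > 0,
                                counts * np.log(counts / m) - (counts - m),
                                m)
            return np.sign(counts - m) * np.sqrt(2.0 * np.clip(term, 0, None))
        return (m - counts) / sigma

    res = least_squares(residuals, p0, method="lm", max_nfev=20000)
    if not res.success:
        raise FitError(f"decay fit did not converge: {res.message}")
    amps, taus, shift, background = unpack(res.x)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    dof = max(counts.size - res.x.size, 1)
    chi2 = float(np.sum(((_model_counts(time_rel, irf_norm, amps, taus, shift,
                                        background, dt) - counts) / sigma) ** 2)
                 / dof)
    frac = amps / amps.sum()
    return DecayFit(
        lifetimes=taus, amplitudes=frac, shift=float(shift),
        background=float(background), goodness=chi2, n_photons=total,
    )


def mean_lifetime(fit: DecayFit) -> float:
    """Amplitude-weighted mean lifetime (ns)."""
    return fit.mean_lifetime
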