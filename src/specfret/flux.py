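"""Liposome proton-flux trace normalization and quench metrics.

A flux experiment records dye fluorescence over three phases: a baseline
(the maximum, ``f_max``), a quench phase after an ionophore establishes the
driving force, and a floor after a protonophore collapses all gradients
(``f_min``).  Traces are normalized to ``(F(t) - f_min) / (f_max - f_min)``
so that the baseline sits at 1 and the floor at 0 regardless of gain or
offset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import AnnotationError, DegenerateTraceError, FitError, FormatError

__all__ = ["FluxTrace", "read_flux_trace", "normalize_flux", "quench_metrics"]

#: Event labels with special meaning.
VALINOMYCIN = "valinomycin"
CCCP = "cccp"


@dataclass(frozen=True)
class FluxTrace:
    """Time course of dye fluorescence with reagent-addition events."""

    time: np.ndarray  # seconds
    fluorescence: np.ndarray
    events: tuple[tuple[str, float], ...] = ()
    f_max: float = float("nan")
    f_min: float = float("nan")
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "events",
                           tuple((str(l), float(at)) for l, at in self.events))
        if t.size != f.size or t.size < 3:
            raise FormatError("time and fluorescence must align, length >= 3")
        if np.any(np.diff(t) <= 0):
            raise FormatError("time must be strictly increasing")
        for label, at in self.events:
            if not t[0] <= at <= t[-1]:
                raise FormatError(f"event {label!r} at {at}s outside time range")

    def event_time(self, label: str) -> float:
        for lab, at in self.events:
            if lab == label:
                return at
        raise AnnotationError(f"no {label!r} event annotated on trace")


def read_flux_trace(path: str | os.PathLike[str],
                    events_path: str | os.PathLike[str] | None = None
                    ) -> FluxTrace:
    """Load a time/fluorescence CSV plus an optional ``label,time`` sidecar."""
    from .spectra import _parse_two_columns

    with open(os.fspath(path), encoding="utf-8") as fh:
        t, f = _parse_two_columns(fh.read(), os.fspath(path))
    events: list[tuple[str, float]] = []
    if events_path is not None:
        with open(os.fspath(events_path), encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, _, at = line.replace("\t", ",").partition(",")
                try:
                    events.append((label.strip().lower(), float(at)))
                except ValueError:
                    continue  # header
    return FluxTrace(time=t, fluorescence=f, events=tuple(events))


def _window_mean(trace: FluxTrace, window: tuple[float, float]) -> float:
    # half-open so a phase boundary sample never leaks into the window
    lo, hi = window
    mask = (trace.time >= lo) & (trace.time < hi)
    if not np.any(mask):
        raise FormatError(f"window {window} contains no samples")
    return float(np.mean(trace.fluorescence[mask]))


def normalize_flux(
    trace: FluxTrace,
    baseline_window: tuple[float, float] | None = None,
    floor_window: tuple[float, float] | None = None,
    floor_delay: float = 10.0,
    floor_span: float = 30.0,
) -> FluxTrace:
    """Normalize to ``(F(t) - f_min) / (f_max - f_min)``.

    ``f_max`` is the mean over the baseline window (default: start of trace
    up to the valinomycin event) and ``f_min`` the mean over a
    ``floor_span``-second window beginning ``floor_delay`` seconds after
    the CCCP event.  Windows may be given explicitly and must not overlap.
    """
    if baseline_window is None:
        baseline_window = (float(trace.time[0]), trace.event_time(VALINOMYCIN))
    if floor_window is None:
        t_cccp = trace.event_time(CCCP)
        floor_window = (t_cccp + floor_delay,
                        min(t_cccp + floor_delay + floor_span, float(trace.time[-1])))
    if baseline_window[1] > floor_window[0]:
        raise FormatError("baseline and floor windows overlap")
    f_max = _window_mean(trace, baseline_window)
    f_min = _window_mean(trace, floor_window)
    if f_max <= f_min:
        raise DegenerateTraceError(
            f"f_max ({f_max:.4g}) <= f_min ({f_min:.4g}): no dynamic range"
        )
    norm = (trace.fluorescence - f_min) / (f_max - f_min)
    return replace(trace, f_max=f_max, f_min=f_min, normalized=norm)


def quench_metrics(
    trace: FluxTrace,
    plateau_span: float = 30.0,
) -> dict[str, float]:
    """Quench extent and rate from a normalized trace.

    ``extent`` is ``1 - mean(normalized)`` over the last ``plateau_span``
    seconds before the CCCP addition; ``rate`` (1/s) comes from a
    single-exponential fit of the post-valinomycin segment
    ``c + A exp(-rate * (t - t_val))``.  Rates faster than the sampling
    interval can resolve are reported at the bound ``1 / dt``.
    """
    if trace.normalized is None:
        raise AnnotationError("call normalize_flux before quench_metrics")
    t_val = trace.event_time(VALINOMYCIN)
    t_cccp = trace.event_time(CCCP)
    norm = trace.normalized
    plateau = (trace.time >= t_cccp - plateau_span) & (trace.time < t_cccp)
    if not np.any(plateau):
        raise FormatError("no samples in pre-CCCP plateau window")
    extent = 1.0 - float(np.mean(norm[plateau]))

    seg = (trace.time >= t_val) & (trace.time < t_cccp)
    ts = trace.time[seg] - t_val
    ys = norm[seg]
    if ts.size < 4:
        raise FitError("too few samples between valinomycin and CCCP")
    dt = float(np.median(np.diff(trace.time)))
    rate_bound = 1.0 / dt

    def model(t, c, a, k):
        return c + a * np.exp(-k * t)

    drop = float(ys[0] - ys[-1])
    try:
        popt, _ = curve_fit(
            model, ts, ys,
            p0=[float(ys[-1]), max(drop, 1e-3), 0.05],
            bounds=([-1.0, 0.0, 1e-6], [2.0, 2.0, 10.0 * rate_bound]),
            maxfev=20000,
        )
        rate = float(popt[2])
    except RuntimeError as exc:
        raise FitError(f"quench-rate fit failed: {exc}") from exc
    return {"extent": extent, "rate": min(rate, rate_bound),
            "rate_bound": rate_bound}
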