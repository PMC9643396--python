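"""Circadian rhythm extraction and protein-degradation kinetics.

Bioluminescence reporter traces (e.g. *Bmal1*-dLuc cells read every 30 min
for days) are detrended and fit with a damped cosine

    y(t) = c + A * exp(-lambda * t) * cos(2*pi*(t - phi)/T)

yielding period T (h), amplitude A, damping lambda (1/h) and phase phi (h).
Cycloheximide-chase decay traces are fit with a one-phase exponential decay

    y(t) = (y0 - p) * exp(-k t) + p

whose half-life is t1/2 = ln2 / k; treated half-lives are reported
normalized to the control-arm mean.

Rhythmicity is decided by an F-test of the damped-cosine model against a
constant at alpha = 0.05; this criterion is this package's own (commercial
rhythm-analysis software does not publish one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import AnalysisError, UnidentifiableFitError

__all__ = [
    "LuminescenceTrace",
    "RhythmFit",
    "DecayFit",
    "detrend",
    "fit_rhythm",
    "fit_decay",
    "normalized_halflife",
]

DEFAULT_PERIOD_BOUNDS = (16.0, 40.0)  # circadian search window, h


@dataclass
class LuminescenceTrace:
    time: np.ndarray  # h, strictly increasing
    signal: np.ndarray  # counts (arbitrary units)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 2:
            raise AnalysisError("trace needs at least 2 points")
        if self.time.shape != self.signal.shape:
            raise AnalysisError("time and signal must have identical shape")
        if np.any(np.diff(self.time) <= 0):
            raise AnalysisError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class RhythmFit:
    period: float | None  # h
    amplitude: float | None
    damping: float | None  # 1/h, >= 0
    phase: float | None  # h
    baseline: float | None
    sse: float | None
    rhythmic: bool
    p_value: float | None = None
    message: str = ""


@dataclass
class DecayFit:
    k: float | None  # 1/h
    t_half: float | None  # h, ln2/k
    y0: float | None
    plateau: float | None
    sse: float | None
    identifiable: bool
    message: str = ""


def detrend(trace: LuminescenceTrace, window: float = 24.0) -> LuminescenceTrace:
    """Subtract a centered moving average of width ``window`` hours.

    The first and last half-window, where the average is not fully supported,
    are trimmed.  Requires (roughly) uniform sampling, as produced by plate
    readers.
    """
    if trace.duration <= window:
        raise AnalysisError(
            f"trace duration {trace.duration:.1f} h must exceed the "
            f"detrending window {window:.1f} h"
        )
    t, y = trace.time, trace.signal
    step = float(np.median(np.diff(t)))
    half = int(round(window / (2.0 * step)))
    if half < 1:
        raise AnalysisError("window shorter than the sampling step")
    width = 2 * half + 1
    kernel = np.ones(width) / width
    baseline = np.convolve(y, kernel, mode="valid")  # length n - width + 1
    interior = slice(half, len(y) - half)
    return LuminescenceTrace(
        time=t[interior],
        signal=y[interior] - baseline,
        metadata={**trace.metadata, "detrended_window_h": window},
    )


def _periodogram_period(t, y, bounds) -> float:
    """Initial period via an oversampled cosine periodogram within bounds."""
    periods = np.linspace(bounds[0], bounds[1], 241)
    # Lomb-Scargle handles the (possibly trimmed) grid without assumptions
    from scipy.signal import lombscargle

    freqs = 2.0 * np.pi / periods
    power = lombscargle(t, y - y.mean(), freqs)
    return float(periods[int(np.argmax(power))])


def _damped_cosine(t, amplitude, damping, period, phase, baseline):
    return baseline + amplitude * np.exp(-damping * t) * np.cos(
        2.0 * np.pi * (t - phase) / period
    )


def fit_rhythm(
    trace: LuminescenceTrace,
    period_bounds: tuple[float, float] = DEFAULT_PERIOD_BOUNDS,
    alpha: float = 0.05,
) -> RhythmFit:
    """Fit a damped cosine to a (detrended) trace and test rhythmicity.

    Nonlinear least squares with the period seeded from the periodogram peak
    inside ``period_bounds``.  ``rhythmic`` is False when the cosine model
    does not beat a constant fit in an F-test at ``alpha``, or when the
    optimizer fails.
    """
    t = trace.time - trace.time[0]
    y = trace.signal
    lo, hi = period_bounds
    if trace.duration < 2.0 * lo:
        raise AnalysisError("trace must span at least two candidate periods")
    p0_period = _periodogram_period(t, y, period_bounds)
    amp0 = float(np.std(y)) * math.sqrt(2.0)
    if amp0 == 0.0:
        return RhythmFit(None, None, None, None, float(y.mean()), 0.0, False,
                         p_value=1.0, message="constant signal")
    p0 = (amp0, 0.01, p0_period, float(t[int(np.argmax(y))] % p0_period), float(y.mean()))
    bounds = (
        [0.0, 0.0, lo, -hi, -np.inf],
        [np.inf, 2.0, hi, hi, np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            _damped_cosine, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return RhythmFit(None, None, None, None, None, None, False,
                         message=f"fit did not converge: {exc}")
    amplitude, damping, period, phase, baseline = (float(v) for v in popt)
    resid = y - _damped_cosine(t, *popt)
    sse = float(np.sum(resid**2))
    sse0 = float(np.sum((y - y.mean()) ** 2))
    n, p_full, p_null = len(y), 5, 1
    if sse <= 0.0 or n <= p_full:
        p_value = 0.0
    else:
        f_stat = ((sse0 - sse) / (p_full - p_null)) / (sse / (n - p_full))
        p_value = float(stats.f.sf(f_stat, p_full - p_null, n - p_full))
    # report phase on the absolute time axis, folded into [0, period)
    phase = (phase + trace.time[0]) % period
    rhythmic = p_value < alpha and amplitude > 0.0
    return RhythmFit(
        period=period,
        amplitude=amplitude,
        damping=damping,
        phase=phase,
        baseline=baseline,
        sse=sse,
        rhythmic=rhythmic,
        p_value=p_value,
    )


def _exp_decay(t, y0, k, plateau):
    return (y0 - plateau) * np.exp(-k * t) + plateau


def fit_decay(trace: LuminescenceTrace, plateau_mode: str = "free") -> DecayFit:
    """One-phase exponential decay fit; ``plateau_mode="zero"`` pins p = 0.

    The trace is taken to start at chase time 0 (translation-inhibitor
    addition).  A flat trace or a non-positive rate estimate is reported as
    unidentifiable rather than raised.
    """
    if plateau_mode not in ("free", "zero"):
        raise ValueError(f"unknown plateau_mode {plateau_mode!r}")
    t = trace.time - trace.time[0]
    y = trace.signal
    span = float(y.max() - y.min())
    if span <= 0.0 or span < 1e-12 * max(abs(float(y.mean())), 1.0):
        return DecayFit(None, None, float(y[0]), float(y[-1]), 0.0, False,
                        message="flat trace: decay rate unidentifiable")
    # crude initial rate from the 1/e crossing of the range
    k0 = 1.0 / max(float(t[-1]) / 3.0, 1e-6)
    try:
        if plateau_mode == "zero":
            popt, _ = optimize.curve_fit(
                lambda tt, y0, k: _exp_decay(tt, y0, k, 0.0),
                t, y, p0=(float(y[0]), k0), maxfev=20000,
            )
            y0_fit, k = (float(v) for v in popt)
            plateau = 0.0
        else:
            popt, _ = optimize.curve_fit(
                _exp_decay, t, y,
                p0=(float(y[0]), k0, float(y[-1])), maxfev=20000,
            )
            y0_fit, k, plateau = (float(v) for v in popt)
    except RuntimeError as exc:
        return DecayFit(None, None, None, None, None, False,
                        message=f"fit did not converge: {exc}")
    resid = y - _exp_decay(t, y0_fit, k, plateau)
    sse = float(np.sum(resid**2))
    if k <= 0.0:
        return DecayFit(None, None, y0_fit, plateau, sse, False,
                        message="non-positive rate estimate")
    return DecayFit(
        k=k, t_half=math.log(2.0) / k, y0=y0_fit, plateau=plateau,
        sse=sse, identifiable=True,
    )


def normalized_halflife(
    treated: Sequence[DecayFit], control: Sequence[DecayFit]
) -> dict:
    """Treated half-lives relative to the mean control half-life.

    Returns the per-replicate ratios plus mean and SEM.  All fits must be
    identifiable.
    """
    if not treated or not control:
        raise AnalysisError("need at least one fit per arm")
    for f in (*treated, *control):
        if not f.identifiable or f.t_half is None:
            raise UnidentifiableFitError("normalized_halflife requires identifiable fits")
    control_mean = float(np.mean([f.t_half for f in control]))
    if control_mean <= 0.0:
        raise AnalysisError("control mean half-life must be positive")
    ratios = np.array([f.t_half / control_mean for f in treated])
    sem = float(ratios.std(ddof=1) / math.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sem": sem,
        "control_mean_t_half": control_mean,
    }
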