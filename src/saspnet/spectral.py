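"""Fourier and envelope analysis of ensemble-averaged node time series.

The ensemble-averaged calcium trace of a finite deterministic network is
exactly periodic once every contributing trajectory has reached its
attractor; its period (the *recurrent module*) is the least common multiple
of the contributing attractor periods.  A plain periodogram of the
mean-centered series therefore consists of sharp lines at rational
frequencies, which motivates three quantities used throughout the analyses:

* the dominant spectral lines and the integer periods they correspond to;
* the *mode diversity* — the number of lines above a power threshold,
  a regularity metric for comparing perturbed networks with the wild type;
* running-average envelopes: averaging an exactly p-periodic series over a
  window of p steps flattens it completely, so a window chosen as one
  component's period reveals the slower envelope contributed by the others.

Frequencies are in cycles per simulation step, in ``(0, 1/2]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumResult",
    "SpectralLine",
    "power_spectrum",
    "dominant_periods",
    "mode_diversity",
    "running_average",
    "recurrent_module_length",
]


@dataclass(frozen=True)
class SpectralLine:
    frequency: float
    power: float
    period: int  # nearest integer period 1/f
    harmonic_of: int | None = None  # fundamental period, if this line is a harmonic


@dataclass(frozen=True)
class SpectrumResult:
    """Periodogram of a mean-centered series; zero frequency excluded."""

    frequencies: np.ndarray
    power: np.ndarray
    n_steps: int
    dominant_modes: tuple[SpectralLine, ...] = ()

    @property
    def total_power(self) -> float:
        """Sum of line powers; equals the analyzed window's variance."""
        return float(self.power.sum())


def _as_array(series) -> np.ndarray:
    values = getattr(series, "values", series)
    return np.asarray(values, dtype=np.float64)


def power_spectrum(
    series,
    n_steps: int = 1000,
    trim_to_module: bool = True,
    threshold_frac: float = 0.05,
    tol: float = 1e-9,
) -> SpectrumResult:
    """Periodogram over the first ``n_steps`` points of a steady-state series.

    The estimator is a plain periodogram (no taper): the signals analyzed
    here are exactly periodic, so leakage control is unnecessary and line
    positions should land exactly on rational frequencies.  To guarantee
    that, when ``trim_to_module`` is set and the series' recurrent module
    *m* is detectable, the window is trimmed to the largest multiple of *m*
    not exceeding ``n_steps``.

    Power is normalized so that the sum over lines equals the variance of
    the analyzed window (Parseval).  ``dominant_modes`` lists lines with
    power at least ``threshold_frac`` of the maximum.
    """
    x = _as_array(series)
    if x.size < n_steps:
        raise ValueError(f"series has {x.size} points, needs >= {n_steps}")
    x = x[:n_steps]
    if trim_to_module:
        m = recurrent_module_length(x, tol=tol)
        if m is not None and m >= 1:
            x = x[: (x.size // m) * m]
    n = x.size
    x = x - x.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n)[1:]
    amp2 = np.abs(spec[1:]) ** 2 / n**2
    # one-sided power: double every bin except a Nyquist bin at f = 1/2
    power = 2.0 * amp2
    if n % 2 == 0:
        power[-1] = amp2[-1]
    result = SpectrumResult(frequencies=freqs, power=power, n_steps=n)
    modes = _dominant_lines(result, threshold_frac)
    return SpectrumResult(
        frequencies=freqs, power=power, n_steps=n, dominant_modes=modes
    )


def _dominant_lines(spec: SpectrumResult, threshold_frac: float) -> tuple[SpectralLine, ...]:
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    pmax = spec.power.max() if spec.power.size else 0.0
    if pmax <= 1e-18:  # numerically silent spectrum (constant series)
        return ()
    keep = np.flatnonzero(spec.power >= threshold_frac * pmax)
    keep = keep[np.argsort(-spec.power[keep], kind="stable")]
    # fundamentals first (ascending frequency) for harmonic attribution
    by_freq = sorted(keep, key=lambda k: spec.frequencies[k])
    fundamentals: list[float] = []
    harmonic_of: dict[int, int | None] = {}
    for k in by_freq:
        f = spec.frequencies[k]
        parent = None
        for f0 in fundamentals:
            ratio = f / f0
            if abs(ratio - round(ratio)) < 1e-6 and round(ratio) >= 2:
                parent = int(round(1.0 / f0))
                break
        if parent is None:
            fundamentals.append(f)
        harmonic_of[k] = parent
    return tuple(
        SpectralLine(
            frequency=float(spec.frequencies[k]),
            power=float(spec.power[k]),
            period=int(round(1.0 / spec.frequencies[k])),
            harmonic_of=harmonic_of[k],
        )
        for k in keep
    )


def dominant_periods(spec: SpectrumResult, threshold_frac: float = 0.05) -> list[int]:
    """Integer periods of the retained fundamental lines, strongest first.

    Lines identified as harmonics of a retained fundamental are attributed
    to that fundamental rather than reported as separate periods.
    """
    if spec.power.size == 0:
        raise ValueError("empty spectrum")
    lines = (
        spec.dominant_modes
        if spec.dominant_modes
        else _dominant_lines(spec, threshold_frac)
    )
    periods: list[int] = []
    for line in lines:
        p = line.harmonic_of if line.harmonic_of is not None else line.period
        if p not in periods:
            periods.append(p)
    return periods


def mode_diversity(spec: SpectrumResult, threshold_frac: float = 0.05) -> int:
    """Number of spectral lines with power >= threshold_frac * max power."""
    if spec.power.size == 0:
        return 0
    pmax = spec.power.max()
    if pmax <= 1e-18:
        return 0
    return int(np.count_nonzero(spec.power >= threshold_frac * pmax))


def running_average(series, w: int) -> np.ndarray:
    """Sliding arithmetic mean; output length = input length - w + 1."""
    x = _as_array(series)
    if w < 1:
        raise ValueError("window must be >= 1")
    if x.size < w:
        raise ValueError(f"window {w} exceeds series length {x.size}")
    c = np.cumsum(np.concatenate(([0.0], x)))
    return (c[w:] - c[:-w]) / w


def recurrent_module_length(series, tol: float = 1e-9) -> int | None:
    """Smallest p with ``|x[t+p] - x[t]| <= tol`` for every valid t.

    For the exact ensemble average of a mixture of attractors this is the
    least common multiple of the contributing periods.  Returns ``None``
    when no p up to half the series length qualifies (aperiodic at this
    scale).
    """
    x = _as_array(series)
    for p in range(1, x.size // 2 + 1):
        if np.max(np.abs(x[p:] - x[:-p])) <= tol:
            return p
    return None
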