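"""Quantify the qualitative behaviors of simulation traces.

Claims about concentration-versus-time curves are usually read by eye —
"these pools oscillate", "monoterpene production decelerates". These functions
give such statements operational definitions on sampled traces: prominent-peak
counting for oscillation, windowed growth-rate drop for deceleration, and
terminal fold changes for perturbation-versus-control comparisons. All
analyses are pure functions of a trace; nothing here re-simulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import Trace

DEFAULT_PROMINENCE = 1.0   # unit
DEFAULT_WINDOW = 10.0      # pt
DEFAULT_DROP_FRACTION = 0.5


@dataclass(frozen=True)
class BehaviorReport:
    species: str
    n_peaks: int
    monotone: bool
    deceleration_time: Optional[float]
    terminal_value: float


def count_peaks(trace: Trace, species: str, prominence: float = DEFAULT_PROMINENCE) -> int:
    """Number of strict local maxima standing at least ``prominence`` above
    both neighboring minima (series minima between adjacent strict maxima,
    or the series ends)."""
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    y = np.asarray(trace[species], dtype=float)
    if y.size < 3:
        return 0
    interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
    if interior.size == 0:
        return 0
    count = 0
    bounds = [0, *interior.tolist(), y.size - 1]
    for k in range(1, len(bounds) - 1):
        i = bounds[k]
        left_min = float(np.min(y[bounds[k - 1]:i + 1]))
        right_min = float(np.min(y[i:bounds[k + 1] + 1]))
        if y[i] - max(left_min, right_min) >= prominence:
            count += 1
    return count


def is_monotone_nondecreasing(trace: Trace, species: str, tol: float = 1e-9) -> bool:
    """True iff every successive difference is >= -tol."""
    y = np.asarray(trace[species], dtype=float)
    return bool(np.all(np.diff(y) >= -tol))


def growth_rate(trace: Trace, species: str) -> np.ndarray:
    """Centered finite-difference growth rate on the sampled points (unit/pt)."""
    y = np.asarray(trace[species], dtype=float)
    return np.gradient(y, trace.times)


def rate_trace(trace: Trace, species: str) -> Trace:
    """A derived single-species trace of the growth rate, for peak analysis of
    production-rate oscillations (e.g. alternating fast/slow sesquiterpene
    growth phases)."""
    return Trace(times=trace.times,
                 series={species: growth_rate(trace, species)},
                 meta={**trace.meta, "derived": f"growth_rate({species})"})


def deceleration_time(trace: Trace, species: str, window: float = DEFAULT_WINDOW,
                      drop_fraction: float = DEFAULT_DROP_FRACTION) -> Optional[float]:
    """Earliest sampled time whose windowed mean growth rate falls below
    ``drop_fraction`` times the maximum windowed rate seen before it.

    Returns ``None`` if the rate never drops that far (e.g. any exactly linear
    series). ``window`` is in pt and must span at least 3 samples.
    """
    if not (0 < drop_fraction < 1):
        raise ValueError("drop_fraction must lie strictly between 0 and 1")
    trace[species]  # unknown species -> hard error before anything else
    times = np.asarray(trace.times, dtype=float)
    if times.size < 3:
        return None
    sample_dt = float(np.median(np.diff(times)))
    half = max(1, int(round(window / sample_dt / 2)))
    if 2 * half + 1 > times.size:
        raise ValueError("window must span at least 3 samples within the trace")
    rates = growth_rate(trace, species)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    windowed = np.convolve(rates, kernel, mode="valid")  # centered windows
    w_times = times[half:times.size - half]
    best = -np.inf
    for t, r in zip(w_times, windowed):
        if best > 0 and r < drop_fraction * best:
            return float(t)
        best = max(best, r)
    return None


def terminal_fold_change(a: Trace, b: Trace, species: str) -> float:
    """terminal(a) / terminal(b); hard error when the control terminal is 0."""
    denom = b.terminal(species)
    if denom == 0:
        raise ZeroDivisionError(
            f"terminal value of {species!r} in the reference trace is zero")
    return a.terminal(species) / denom


def behavior_report(trace: Trace, species: str,
                    prominence: float = DEFAULT_PROMINENCE,
                    window: float = DEFAULT_WINDOW,
                    drop_fraction: float = DEFAULT_DROP_FRACTION) -> BehaviorReport:
    return BehaviorReport(
        species=species,
        n_peaks=count_peaks(trace, species, prominence),
        monotone=is_monotone_nondecreasing(trace, species),
        deceleration_time=deceleration_time(trace, species, window, drop_fraction),
        terminal_value=trace.terminal(species),
    )
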