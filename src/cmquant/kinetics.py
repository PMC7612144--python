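"""Per-beat kinetics of paced cardiomyocyte traces.

Sarcomere-shortening traces yield resting and peak sarcomere length, peak
shortening (% of resting), maximum departure/return velocities (from the
central-difference dSL/dt) and time to peak. Fura-2 ratio traces yield
basal, amplitude, calcium release/reuptake speeds, elevation time
(stimulus to peak) and reuptake time (peak to 50 % decay).

Stimuli are assumed at multiples of the pacing period starting at t = 0
(no trigger channel is exported by the acquisition system), so beats are
fixed windows of one period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class Trace:
    """Uniformly sampled time series of a paced cell."""

    time: np.ndarray
    value: np.ndarray
    stim_freq: float = 2.0
    kind: str = "sarcomere"  # sarcomere | fluorescence | ratio

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be equal-length 1-D arrays")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if dt.min() <= 0:
                raise ValueError("time must be strictly increasing")
            if (dt.max() - dt.min()) > 1e-9 * dt.mean():
                raise ValueError("sampling interval must be constant")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass(frozen=True)
class BeatSegment:
    start: int
    end: int  # exclusive


@dataclass(frozen=True)
class SarcomereKinetics:
    resting_sl: float
    peak_shortening_pct: float
    max_departure_velocity: float
    max_return_velocity: float
    time_to_peak: float


@dataclass(frozen=True)
class CalciumKinetics:
    basal: float
    amplitude: float
    release_speed: float
    reuptake_speed: float
    elevation_time: float
    reuptake_time: float


def compute_fura_ratio(f360: Trace, f380: Trace) -> Trace:
    """Pointwise 360/380 excitation ratio."""
    if f360.time.shape != f380.time.shape or not np.allclose(
            f360.time, f380.time, rtol=0, atol=1e-12):
        raise ValueError("time grids differ between excitation channels")
    zeros = np.nonzero(f380.value == 0.0)[0]
    if zeros.size:
        raise ValueError(f"zero denominator at sample index {zeros[0]}")
    return Trace(time=f360.time.copy(), value=f360.value / f380.value,
                 stim_freq=f360.stim_freq, kind="ratio")


def segment_beats(trace: Trace) -> list[BeatSegment]:
    """Fixed one-period windows starting at t = 0; trailing partial window
    discarded."""
    beat_len = int(round(trace.sample_rate / trace.stim_freq))
    n_beats = trace.time.size // beat_len
    if n_beats < 1:
        raise ValueError("trace shorter than one stimulation period")
    return [BeatSegment(i * beat_len, (i + 1) * beat_len)
            for i in range(n_beats)]


def beat_trace(trace: Trace, segment: BeatSegment) -> Trace:
    """Extract one stimulus-aligned beat (time rebased to 0)."""
    t = trace.time[segment.start:segment.end]
    return Trace(time=t - t[0], value=trace.value[segment.start:segment.end],
                 stim_freq=trace.stim_freq, kind=trace.kind)


def average_beat(beats: list[Trace]) -> Trace:
    """Pointwise mean across stimulus-aligned beats."""
    if not beats:
        raise ValueError("no beats to average")
    n = min(b.value.size for b in beats)
    stacked = np.stack([b.value[:n] for b in beats])
    return Trace(time=beats[0].time[:n], value=stacked.mean(axis=0),
                 stim_freq=beats[0].stim_freq, kind=beats[0].kind)


def _baseline_window(n: int, frac: float, where: str) -> slice:
    w = max(1, int(round(frac * n)))
    return slice(n - w, n) if where == "pre_stimulus" else slice(0, w)


def sarcomere_kinetics(beat: Trace, baseline_frac: float = 0.05,
                       baseline_at: str = "pre_stimulus",
                       smooth_window: int | None = None) -> SarcomereKinetics:
    """Kinetic metrics of one (or one averaged) sarcomere beat.

    Resting length is the median over the diastolic baseline window — by
    default the final ``baseline_frac`` of the beat, i.e. the pre-stimulus
    interval of the next beat, since contraction begins at the stimulus
    itself (``baseline_at='onset'`` uses the leading window instead).
    Velocities are magnitudes of the central-difference dSL/dt, split at the
    shortening peak; ties at the peak break to the earliest sample.
    """
    if beat.kind != "sarcomere":
        raise ValueError(f"expected a sarcomere trace, got kind={beat.kind!r}")
    value = _maybe_smooth(beat.value, smooth_window)
    n = value.size
    resting = float(np.median(value[_baseline_window(n, baseline_frac,
                                                     baseline_at)]))
    i_pk = int(np.argmin(value))
    peak = float(value[i_pk])
    shortening = max(0.0, (resting - peak) / resting * 100.0)
    dt = beat.time[1] - beat.time[0]
    deriv = np.gradient(value, dt)
    departure = float(max(0.0, -deriv[: i_pk + 1].min())) if i_pk > 0 else 0.0
    ret = float(max(0.0, deriv[i_pk:].max())) if i_pk < n - 1 else 0.0
    return SarcomereKinetics(
        resting_sl=resting, peak_shortening_pct=shortening,
        max_departure_velocity=departure, max_return_velocity=ret,
        time_to_peak=float(beat.time[i_pk] - beat.time[0]),
    )


def calcium_kinetics(beat: Trace, baseline_frac: float = 0.05,
                     baseline_at: str = "onset", decay_frac: float = 0.5,
                     smooth_window: int | None = None) -> CalciumKinetics:
    """Kinetic metrics of one (or one averaged) calcium-ratio beat.

    Basal defaults to the stimulus-onset sample window (the transient decays
    only asymptotically, so the onset instant is the unbiased basal estimate
    on this model; ``baseline_at='pre_stimulus'`` uses the trailing window).
    Reuptake time is the linearly interpolated first crossing of
    basal + ``decay_frac`` * amplitude after the peak (default 50 % decay).
    """
    if beat.kind != "ratio":
        raise ValueError(f"expected a ratio trace, got kind={beat.kind!r}")
    value = _maybe_smooth(beat.value, smooth_window)
    n = value.size
    if baseline_at == "onset":
        # the upstroke starts immediately after the stimulus, so only the
        # onset sample itself sits at basal
        basal = float(value[0])
    else:
        basal = float(np.median(value[_baseline_window(n, baseline_frac,
                                                       "pre_stimulus")]))
    i_pk = int(np.argmax(value))
    amplitude = max(0.0, float(value[i_pk]) - basal)
    dt = beat.time[1] - beat.time[0]
    release = float(max(0.0, np.diff(value[: i_pk + 1]).max() / dt)) \
        if i_pk > 0 else 0.0
    reuptake = float(max(0.0, -np.diff(value[i_pk:]).min() / dt)) \
        if i_pk < n - 1 else 0.0
    elevation_time = float(beat.time[i_pk] - beat.time[0])

    reuptake_time = float("nan")
    if i_pk >= n - 1 or amplitude == 0.0:
        warnings.warn("no decay phase after the peak; reuptake time undefined",
                      stacklevel=2)
    else:
        target = basal + (1.0 - decay_frac) * amplitude
        post = value[i_pk:]
        below = np.nonzero(post <= target)[0]
        if below.size == 0:
            warnings.warn("trace never decays to the target level; "
                          "reuptake time undefined", stacklevel=2)
        else:
            j = int(below[0])
            if j == 0:
                reuptake_time = 0.0
            else:
                y0, y1 = post[j - 1], post[j]
                frac = (y0 - target) / (y0 - y1)
                reuptake_time = float((j - 1 + frac) * dt)
    return CalciumKinetics(
        basal=basal, amplitude=amplitude, release_speed=release,
        reuptake_speed=reuptake, elevation_time=elevation_time,
        reuptake_time=reuptake_time,
    )


def _maybe_smooth(value: np.ndarray, window: int | None) -> np.ndarray:
    if window is None or window <= 1:
        return value
    kernel = np.ones(window) / window
    return np.convolve(value, kernel, mode="same")


def trace_kinetics(trace: Trace, **kwargs):
    """Segment a multi-beat trace, average the beats, and compute kinetics.

    Returns (per-beat list, averaged-beat kinetics).
    """
    beats = [beat_trace(trace, s) for s in segment_beats(trace)]
    fn = sarcomere_kinetics if trace.kind == "sarcomere" else calcium_kinetics
    per_beat = [fn(b, **kwargs) for b in beats]
    avg = fn(average_beat(beats), **kwargs)
    return per_beat, avg
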