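"""Embolism resistance from ultrasonic acoustic emissions.

During bench-top dehydration, cavitating xylem conduits emit ultrasonic
clicks.  Events of >= 35 dB are kept, counted in 5-min bins (acoustic
emission activity, AEA), each bin assigned the plant water potential
linearly interpolated between sparse psychrometer anchor readings, the
binned activity smoothed with a Savitzky-Golay filter, and the water
potential at the main activity peak reported as Psi_AEAmax -- the
potential of maximal embolism formation.

Angiosperms (and very young conifers) often show an almost linear rise
of emissions at low water potentials from non-conductive tissue; a
monotone final rise is therefore excluded from peak candidates unless no
interior peak exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "AEEventStream",
    "PsiTimeline",
    "ActivitySeries",
    "VulnerabilityResult",
    "filter_events",
    "interpolate_psi",
    "bin_activity",
    "smooth_activity",
    "find_psi_aeamax",
    "analyse_stream",
    "BIN_SECONDS",
]

BIN_SECONDS = 300.0  # 5-min activity increments


@dataclass
class AEEventStream:
    """Time-ordered acoustic events (time s, amplitude dB) for one plant."""

    sample_id: str
    events: list[tuple[float, float]]
    amplitude_threshold: float = 35.0  # dB, inclusive

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.sample_id}: event times must be non-decreasing")
        if any(a < 0 for _, a in self.events):
            raise ValueError(f"{self.sample_id}: amplitudes must be >= 0 dB")


@dataclass
class PsiTimeline:
    """Sparse (time s, psi MPa) anchor measurements during dehydration."""

    anchors: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two psi anchors to interpolate")
        times = [t for t, _ in self.anchors]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("anchor times must strictly increase")
        psis = [p for _, p in self.anchors]
        if any(b > a for a, b in zip(psis, psis[1:])):
            warnings.warn(
                "psi anchors increase over time; dehydration should be "
                "monotone",
                stacklevel=2,
            )


@dataclass
class ActivitySeries:
    """Acoustic emission activity per fixed 5-min bin."""

    sample_id: str
    t_mid: np.ndarray  # s
    psi_mid: np.ndarray  # MPa
    counts: np.ndarray  # events per bin
    smoothed: np.ndarray | None = None
    smoothing_skipped: bool = False

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class VulnerabilityResult:
    sample_id: str
    psi_aeamax: float  # MPa
    peaks: list[tuple[float, float, float]]  # (psi, smoothed activity, prominence)
    tail_monotone: bool = False
    n_events: int = 0


def filter_events(stream: AEEventStream) -> AEEventStream:
    """Drop events below the amplitude threshold (>= is inclusive)."""
    kept = [
        (t, a) for t, a in stream.events if a >= stream.amplitude_threshold
    ]
    return AEEventStream(
        sample_id=stream.sample_id,
        events=kept,
        amplitude_threshold=stream.amplitude_threshold,
    )


def interpolate_psi(
    timeline: PsiTimeline, t: float | np.ndarray
) -> float | np.ndarray:
    """Piecewise-linear psi at time(s) t, clamped beyond the anchor span."""
    at = np.array([a[0] for a in timeline.anchors], dtype=float)
    ap = np.array([a[1] for a in timeline.anchors], dtype=float)
    tt = np.asarray(t, dtype=float)
    if np.any(tt < at[0]) or np.any(tt > at[-1]):
        warnings.warn(
            "time outside psi anchor span; clamping to end values",
            stacklevel=2,
        )
    out = np.interp(tt, at, ap)
    return float(out) if np.isscalar(t) else out


def bin_activity(
    stream: AEEventStream,
    timeline: PsiTimeline,
    bin_s: float = BIN_SECONDS,
) -> ActivitySeries:
    """Count threshold-passing events in consecutive half-open bins.

    Bins are [start, start+bin_s) anchored at the first retained event;
    an event exactly on a boundary belongs to the later bin.  Each bin
    carries the interpolated psi at its midpoint.  Total counts are
    conserved.
    """
    filtered = filter_events(stream)
    times = np.array([t for t, _ in filtered.events], dtype=float)
    if times.size == 0:
        return ActivitySeries(
            sample_id=stream.sample_id,
            t_mid=np.empty(0),
            psi_mid=np.empty(0),
            counts=np.empty(0, dtype=int),
        )
    t0 = times[0]
    idx = np.floor((times - t0) / bin_s).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    t_mid = t0 + bin_s * (np.arange(n_bins) + 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        psi_mid = np.asarray(interpolate_psi(timeline, t_mid))
    return ActivitySeries(
        sample_id=stream.sample_id,
        t_mid=t_mid,
        psi_mid=psi_mid,
        counts=counts,
    )


def smooth_activity(
    series: ActivitySeries, window_bins: int = 11, polyorder: int = 3
) -> ActivitySeries:
    """Attach Savitzky-Golay smoothed counts; raw counts untouched.

    The window must be odd and larger than the polynomial order; for
    short series it is shrunk to the largest valid odd length.  Series
    shorter than polyorder + 2 are returned unsmoothed with a flag.
    """
    n = len(series)
    if n < polyorder + 2:
        warnings.warn(
            f"{series.sample_id}: series of {n} bins too short to smooth",
            stacklevel=2,
        )
        return ActivitySeries(
            sample_id=series.sample_id,
            t_mid=series.t_mid,
            psi_mid=series.psi_mid,
            counts=series.counts,
            smoothed=series.counts.astype(float),
            smoothing_skipped=True,
        )
    if window_bins % 2 == 0:
        raise ValueError("window_bins must be odd")
    if window_bins <= polyorder:
        raise ValueError("window_bins must exceed polyorder")
    w = window_bins
    if w > n:
        w = n if n % 2 == 1 else n - 1
        if w <= polyorder:
            # smallest odd window exceeding the order still fits: n >= polyorder+2
            w = polyorder + 1 if (polyorder + 1) % 2 == 1 else polyorder + 2
        warnings.warn(
            f"{series.sample_id}: window shrunk to {w} bins for a "
            f"{n}-bin series",
            stacklevel=2,
        )
    smoothed = savgol_filter(series.counts.astype(float), w, polyorder)
    return ActivitySeries(
        sample_id=series.sample_id,
        t_mid=series.t_mid,
        psi_mid=series.psi_mid,
        counts=series.counts,
        smoothed=smoothed,
    )


def find_psi_aeamax(
    series: ActivitySeries,
    prominence_frac: float = 0.1,
    global_max: bool = False,
) -> VulnerabilityResult:
    """Water potential at the main peak of smoothed acoustic activity.

    Interior local maxima with prominence >= prominence_frac times the
    smoothed maximum are ranked by prominence; the most prominent wins.
    When the smoothed activity rises monotonically into the final bin
    (the non-conductive-tissue tail), that endpoint is excluded from the
    candidates unless no interior maximum exists.  ``global_max=True``
    bypasses peak logic and reports the psi of the smoothed maximum.
    """
    if series.smoothed is None:
        raise ValueError("smooth_activity must be applied first")
    sm = np.asarray(series.smoothed, dtype=float)
    n = len(sm)
    if n < 3:
        raise ValueError("need at least 3 bins to locate a peak")
    if np.allclose(sm, sm[0]):
        raise ValueError("flat activity series has no peak")

    total = int(series.counts.sum())
    tail_monotone = bool(n >= 3 and sm[-1] > sm[-2] > sm[-3])

    if global_max:
        i = int(np.argmax(sm))
        return VulnerabilityResult(
            sample_id=series.sample_id,
            psi_aeamax=float(series.psi_mid[i]),
            peaks=[(float(series.psi_mid[i]), float(sm[i]), float("nan"))],
            tail_monotone=tail_monotone,
            n_events=total,
        )

    idx, props = find_peaks(sm, prominence=prominence_frac * sm.max())
    if idx.size > 0:
        order = np.argsort(props["prominences"])[::-1]
        peaks = [
            (
                float(series.psi_mid[idx[j]]),
                float(sm[idx[j]]),
                float(props["prominences"][j]),
            )
            for j in order
        ]
        return VulnerabilityResult(
            sample_id=series.sample_id,
            psi_aeamax=peaks[0][0],
            peaks=peaks,
            tail_monotone=tail_monotone,
            n_events=total,
        )

    # no interior peak: fall back to the global maximum (possibly the
    # monotone endpoint)
    i = int(np.argmax(sm))
    return VulnerabilityResult(
        sample_id=series.sample_id,
        psi_aeamax=float(series.psi_mid[i]),
        peaks=[(float(series.psi_mid[i]), float(sm[i]), float("nan"))],
        tail_monotone=tail_monotone,
        n_events=total,
    )


def analyse_stream(
    stream: AEEventStream,
    timeline: PsiTimeline,
    window_bins: int = 11,
    polyorder: int = 3,
    prominence_frac: float = 0.1,
    global_max: bool = False,
) -> tuple[VulnerabilityResult, ActivitySeries]:
    """Full per-plant workup: filter, bin, smooth, locate the main peak."""
    series = bin_activity(stream, timeline)
    series = smooth_activity(series, window_bins=window_bins, polyorder=polyorder)
    result = find_psi_aeamax(
        series, prominence_frac=prominence_frac, global_max=global_max
    )
    return result, series
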