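"""Oculomotor event classification from gaze sample streams.

Fixations are detected with a dispersion-threshold (I-DT) scheme using the
deployed classification parameters: a window of consecutive samples is a
fixation iff its angular dispersion stays within 1.50 degrees and its
duration falls in the 80-420 ms range. Dispersion is the maximum pairwise
angular separation of the window's samples (rotation invariant, unlike the
bounding-box sum). Saccades are the shifts between consecutive fixation
centroids; blinks are sustained tracker-confidence dropouts.

Streams are expected to be confidence-filtered before detection. Samples
removed by the filter leave temporal gaps; a gap exceeding twice the
nominal sample interval breaks the fixation window, which is what separates
dwells whose spatial separation alone (often < 0.3 degrees here) would not
exceed the dispersion threshold. Dwells longer than 420 ms are split into
consecutive capped fixations, with a terminal remainder kept only if it
still reaches 80 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "GazeStream",
    "Fixation",
    "Saccade",
    "Blink",
    "SessionMetrics",
    "read_gaze_csv",
    "write_gaze_csv",
    "filter_by_confidence",
    "angular_dispersion",
    "detect_fixations",
    "extract_saccades",
    "detect_blinks",
    "session_metrics",
    "write_events_csv",
]

DEFAULT_MAX_DISPERSION = 1.50  # degrees
DEFAULT_MIN_DURATION = 0.080  # s
DEFAULT_MAX_DURATION = 0.420  # s
DEFAULT_CONFIDENCE_THRESHOLD = 0.6  # tracker confidence, [0, 1]
DEFAULT_SACCADE_MAX_GAP = 0.075  # s; longer inter-fixation gaps are not saccades
GAP_FACTOR = 2.0  # gaps > GAP_FACTOR / nominal_rate break fixation windows


@dataclass(frozen=True)
class GazeStream:
    """Time-ordered gaze samples in scene-frame degrees.

    Arrays are parallel: timestamps (s, strictly increasing), x/y (degrees),
    confidence (fraction in [0, 1]).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    nominal_rate: float = 200.0

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "confidence"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.confidence) == n):
            raise ValueError("t, x, y, confidence must have equal length")
        if n and (np.any(self.confidence < 0) or np.any(self.confidence > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        if n and not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps must be finite")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0


@dataclass(frozen=True)
class Fixation:
    start: float
    end: float
    centroid_x: float
    centroid_y: float
    dispersion: float
    n_samples: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Saccade:
    from_fixation: int
    to_fixation: int
    amplitude: float  # degrees, centroid to centroid
    duration: float  # s, gap between fixation end and next start


@dataclass(frozen=True)
class Blink:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("blink end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SessionMetrics:
    fixation_count: int
    mean_fixation_duration: float  # s; NaN when no fixations
    mean_saccade_amplitude: float  # degrees; NaN when no saccades
    blink_rate: float  # events / minute
    total_duration: float  # s


GAZE_CSV_COLUMNS = ["timestamp", "x_deg", "y_deg", "confidence"]


def read_gaze_csv(path, nominal_rate: float = 200.0) -> GazeStream:
    """Read the `timestamp,x_deg,y_deg,confidence` gaze CSV dialect."""
    df = pd.read_csv(path)
    missing = set(GAZE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    return GazeStream(
        t=df["timestamp"].to_numpy(float),
        x=df["x_deg"].to_numpy(float),
        y=df["y_deg"].to_numpy(float),
        confidence=df["confidence"].to_numpy(float),
        nominal_rate=nominal_rate,
    )


def write_gaze_csv(stream: GazeStream, path) -> None:
    pd.DataFrame(
        {
            "timestamp": stream.t,
            "x_deg": stream.x,
            "y_deg": stream.y,
            "confidence": stream.confidence,
        }
    ).to_csv(path, index=False)


def filter_by_confidence(stream: GazeStream, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> GazeStream:
    """Keep samples with confidence >= threshold, preserving order.

    The result may be empty; downstream detectors accept empty streams.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    keep = stream.confidence >= threshold
    return GazeStream(
        t=stream.t[keep], x=stream.x[keep], y=stream.y[keep],
        confidence=stream.confidence[keep], nominal_rate=stream.nominal_rate,
    )


def angular_dispersion(x, y) -> float:
    """Maximum pairwise angular separation of a sample cloud, in degrees.

    Symmetric under any reordering of the samples; 0 for a single sample.
    Large clouds are reduced to their convex hull first (the diameter of a
    point set is attained between hull vertices).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("need at least one sample")
    if len(x) == 1:
        return 0.0
    pts = np.column_stack([x, y])
    if len(pts) > 400:
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # collinear/degenerate clouds
            pass
    return float(pdist(pts).max())


def _segment_bounds(t: np.ndarray, nominal_rate: float) -> list[tuple[int, int]]:
    """Half-open [i, j) runs of samples not separated by a window-breaking gap."""
    if len(t) == 0:
        return []
    max_gap = GAP_FACTOR / nominal_rate * (1 + 1e-9)
    breaks = np.flatnonzero(np.diff(t) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(t)]))
    return list(zip(starts.tolist(), ends.tolist()))


def _emit(t, x, y, i, j, d, out: list[Fixation]) -> None:
    out.append(
        Fixation(
            start=float(t[i]),
            end=float(t[j]),
            centroid_x=float(np.mean(x[i : j + 1])),
            centroid_y=float(np.mean(y[i : j + 1])),
            dispersion=float(d),
            n_samples=j - i + 1,
        )
    )


_T_EPS = 1e-9  # absolute slack for duration comparisons on float timestamps


def _idt_segment(
    t, x, y, i0, i1, max_dispersion, min_duration, max_duration, out: list[Fixation]
) -> None:
    """Greedy left-to-right I-DT over one gap-free segment [i0, i1)."""
    # Fast path: a whole segment that already fits both limits is one fixation
    # (the common case when confidence gaps delimit individual dwells).
    span = t[i1 - 1] - t[i0]
    if min_duration - _T_EPS <= span <= max_duration + _T_EPS:
        d = float(pdist(np.column_stack([x[i0:i1], y[i0:i1]])).max())
        if d <= max_dispersion:
            _emit(t, x, y, i0, i1 - 1, d, out)
            return

    i = i0
    while i < i1:
        # smallest j with span >= min_duration
        j = int(np.searchsorted(t, t[i] + min_duration - _T_EPS, side="left"))
        if j >= i1:
            return
        d = pdist(np.column_stack([x[i : j + 1], y[i : j + 1]])).max() if j > i else 0.0
        if d > max_dispersion:
            i += 1
            continue
        # expand while dispersion and duration limits hold
        while j + 1 < i1 and t[j + 1] - t[i] <= max_duration + _T_EPS:
            dn = np.hypot(x[i : j + 1] - x[j + 1], y[i : j + 1] - y[j + 1]).max()
            if dn > max_dispersion:
                break
            d = max(d, dn)
            j += 1
        _emit(t, x, y, i, j, float(d), out)
        i = j + 1


def detect_fixations(
    stream: GazeStream,
    max_dispersion: float = DEFAULT_MAX_DISPERSION,
    min_duration: float = DEFAULT_MIN_DURATION,
    max_duration: float = DEFAULT_MAX_DURATION,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    The stream should already be confidence-filtered. Windows are grown
    greedily left to right within gap-free runs (a gap > 2x the nominal
    sample interval breaks the window); each emitted fixation satisfies
    dispersion <= max_dispersion and min_duration <= duration <= max_duration.
    Returns time-ordered, non-overlapping fixations; an empty stream gives
    an empty list.
    """
    if not (max_dispersion > 0 and min_duration > 0 and max_duration > 0):
        raise ValueError("detector parameters must be positive")
    if min_duration >= max_duration:
        raise ValueError("min_duration must be smaller than max_duration")
    if len(stream) == 0:
        return []
    if len(stream) > 1 and np.any(np.diff(stream.t) <= 0):  # defensive; ctor enforces
        raise ValueError("timestamps must be strictly increasing")

    out: list[Fixation] = []
    for i0, i1 in _segment_bounds(stream.t, stream.nominal_rate):
        _idt_segment(
            stream.t, stream.x, stream.y, i0, i1,
            max_dispersion, min_duration, max_duration, out,
        )
    return out


def extract_saccades(
    fixations: list[Fixation],
    max_gap: float | None = DEFAULT_SACCADE_MAX_GAP,
) -> list[Saccade]:
    """Saccades between consecutive fixations (centroid-to-centroid).

    Amplitude is the angular distance between the two centroids on the flat
    degree plane; duration is the gap between the first fixation's end and
    the next one's start. Pairs separated by more than ``max_gap`` seconds
    (default 75 ms — longer gaps are blinks or tracking loss, not saccades)
    are skipped; pass ``max_gap=None`` to pair every consecutive fixation.
    Fewer than two fixations give an empty list.
    """
    sacc: list[Saccade] = []
    for k in range(len(fixations) - 1):
        a, b = fixations[k], fixations[k + 1]
        if b.start < a.end:
            raise ValueError("fixations must be time-ordered and non-overlapping")
        gap = b.start - a.end
        if max_gap is not None and gap > max_gap:
            continue
        amp = math.hypot(b.centroid_x - a.centroid_x, b.centroid_y - a.centroid_y)
        sacc.append(Saccade(from_fixation=k, to_fixation=k + 1, amplitude=amp, duration=gap))
    return sacc


def detect_blinks(
    stream: GazeStream,
    confidence_floor: float = 0.5,
    min_duration: float = 0.1,
) -> list[Blink]:
    """Maximal sub-floor confidence intervals lasting at least min_duration.

    Operates on the raw (unfiltered) stream: blinks are the episodes the
    confidence filter would delete wholesale.
    """
    if not (0 < confidence_floor <= 1) or min_duration <= 0:
        raise ValueError("confidence_floor and min_duration must be positive")
    low = stream.confidence < confidence_floor
    if not low.any():
        return []
    idx = np.flatnonzero(low)
    splits = np.flatnonzero(np.diff(idx) > 1)  # group consecutive indices
    run_starts = np.concatenate(([0], splits + 1))
    run_ends = np.concatenate((splits, [len(idx) - 1]))
    blinks = []
    for rs, re in zip(run_starts, run_ends):
        t0, t1 = stream.t[idx[rs]], stream.t[idx[re]]
        if t1 - t0 >= min_duration * (1 - 1e-9):
            blinks.append(Blink(start=float(t0), end=float(t1)))
    return blinks


def session_metrics(
    fixations: list[Fixation],
    saccades: list[Saccade],
    blinks: list[Blink],
    total_duration: float,
) -> SessionMetrics:
    """Per-session aggregates: counts, arithmetic means, blink rate.

    Means over empty event lists are reported as NaN.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    return SessionMetrics(
        fixation_count=len(fixations),
        mean_fixation_duration=(
            float(np.mean([f.duration for f in fixations])) if fixations else float("nan")
        ),
        mean_saccade_amplitude=(
            float(np.mean([s.amplitude for s in saccades])) if saccades else float("nan")
        ),
        blink_rate=len(blinks) / (total_duration / 60.0),
        total_duration=total_duration,
    )


def write_events_csv(fixations, saccades, blinks, path) -> None:
    """Write detected events as one tidy CSV.

    Columns: kind, start, end, centroid_x, centroid_y, dispersion, duration,
    amplitude (saccade rows carry amplitude; others leave it empty).
    """
    rows = []
    for f in fixations:
        rows.append(
            {"kind": "fixation", "start": f.start, "end": f.end,
             "centroid_x": f.centroid_x, "centroid_y": f.centroid_y,
             "dispersion": f.dispersion, "duration": f.duration, "amplitude": np.nan}
        )
    for s in saccades:
        a = fixations[s.from_fixation]
        b = fixations[s.to_fixation]
        rows.append(
            {"kind": "saccade", "start": a.end, "end": b.start,
             "centroid_x": np.nan, "centroid_y": np.nan, "dispersion": np.nan,
             "duration": s.duration, "amplitude": s.amplitude}
        )
    for b in blinks:
        rows.append(
            {"kind": "blink", "start": b.start, "end": b.end,
             "centroid_x": np.nan, "centroid_y": np.nan, "dispersion": np.nan,
             "duration": b.duration, "amplitude": np.nan}
        )
    df = pd.DataFrame(
        rows,
        columns=["kind", "start", "end", "centroid_x", "centroid_y",
                 "dispersion", "duration", "amplitude"],
    )
    df.sort_values(["start", "kind"], inplace=True, kind="mergesort")
    df.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
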