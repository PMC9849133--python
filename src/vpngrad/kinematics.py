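"""Behavioural and physiological metrics.

Track preprocessing and takeoff vectors for high-speed escape videos
(tracked at 600 Hz), circular statistics of takeoff direction (mean
resultant length and the Hodges-Ajne uniformity test), the pre-takeoff
postural-lean angle of the middle (T2) jumping legs, and whole-cell
recording metrics (slope-threshold spike detection and the integrated
depolarization over the response window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

#: tracked-video sampling interval (600 Hz subsampling)
TRACK_RATE_HZ = 600.0

COM = "com"
T2_LEFT = "t2_left"
T2_RIGHT = "t2_right"
HEAD = "head"
ABDOMEN = "abdomen"


@dataclass
class TrackedSequence:
    """Per-frame labelled 2D points from one camera view.

    ``points`` maps a label to an ``(n_frames, 2)`` float array; missing
    detections are NaN.  Timestamps are seconds and strictly increasing.
    """

    timestamps: np.ndarray
    points: dict
    view: str = "side"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        n = len(self.timestamps)
        self.points = {k: np.asarray(v, float).reshape(n, 2) for k, v in self.points.items()}

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def frame_at(self, t: float) -> int:
        return int(np.argmin(np.abs(self.timestamps - t)))


@dataclass
class TakeoffEvent:
    t_start: float
    t_end: float
    com_start: np.ndarray
    com_end: np.ndarray
    direction_deg: float
    magnitude: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")


@dataclass
class EphysTrace:
    """Membrane-potential trace with baseline and response windows.

    Baseline = 2 s before stimulus onset; response = 150 ms after onset.
    """

    samples_mv: np.ndarray
    rate_khz: float
    stimulus_onset_ms: float
    baseline_window_ms: float = 2000.0
    response_window_ms: float = 150.0

    def __post_init__(self):
        self.samples_mv = np.asarray(self.samples_mv, float)
        if self.rate_khz <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration_ms(self) -> float:
        return len(self.samples_mv) / self.rate_khz

    def _idx(self, t_ms: float) -> int:
        return int(round(t_ms * self.rate_khz))

    def baseline_slice(self) -> slice:
        lo = max(0, self._idx(self.stimulus_onset_ms - self.baseline_window_ms))
        hi = self._idx(self.stimulus_onset_ms)
        if hi <= lo:
            raise ValueError("empty baseline window")
        return slice(lo, hi)

    def response_slice(self) -> slice:
        lo = self._idx(self.stimulus_onset_ms)
        hi = self._idx(self.stimulus_onset_ms + self.response_window_ms)
        if hi > len(self.samples_mv):
            raise ValueError("response window exceeds trace")
        if hi <= lo:
            raise ValueError("empty response window")
        return slice(lo, hi)


# ---------------------------------------------------------------------------
# track preprocessing


def _interpolate_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs strictly shorter than ``max_gap``."""
    x = x.astype(float).copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    idx = np.arange(len(x))
    # find NaN runs
    run_start = None
    for i in range(len(x) + 1):
        if i < len(x) and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            interior = run_start > 0 and i < len(x)
            if interior and run_len < max_gap:
                x[run_start:i] = np.interp(
                    idx[run_start:i], [run_start - 1, i], [x[run_start - 1], x[i]]
                )
            run_start = None
    return x


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over valid (non-NaN) samples; NaNs stay NaN."""
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.full_like(x, np.nan, dtype=float)
    for i in range(len(x)):
        if np.isnan(x[i]):
            continue
        seg = x[max(0, i - half) : i + half + 1]
        out[i] = np.nanmean(seg)
    return out


def preprocess_tracks(seq: TrackedSequence, max_gap: int = 5, smooth_window: int = 5) -> TrackedSequence:
    """Fill short occlusion gaps (< ``max_gap`` frames) by linear
    interpolation and smooth with a centered moving average."""
    new_points = {}
    for label, arr in seq.points.items():
        cols = []
        for c in range(2):
            filled = _interpolate_gaps(arr[:, c], max_gap)
            cols.append(_moving_average(filled, smooth_window))
        new_points[label] = np.column_stack(cols)
    return TrackedSequence(seq.timestamps.copy(), new_points, seq.view)


def takeoff_vector(seq: TrackedSequence, t_start: float, t_end: float) -> TakeoffEvent:
    """Takeoff direction and magnitude from the COM displacement between the
    start of jumping-leg extension and the last tarsal contact.

    Direction is measured in the bottom view relative to the body axis at
    ``t_start`` (0 deg = forward, positive = leftward/CCW).  When head and
    abdomen points are absent the +x image axis is taken as forward.
    """
    if COM not in seq.points:
        raise ValueError("sequence has no COM track")
    i0, i1 = seq.frame_at(t_start), seq.frame_at(t_end)
    c0, c1 = seq.points[COM][i0], seq.points[COM][i1]
    if np.any(np.isnan(c0)) or np.any(np.isnan(c1)):
        raise ValueError("COM missing at event time")
    disp = c1 - c0
    mag = float(np.hypot(*disp))
    if mag == 0:
        raise ValueError("zero COM displacement; direction undefined")
    if HEAD in seq.points and ABDOMEN in seq.points:
        axis = seq.points[HEAD][i0] - seq.points[ABDOMEN][i0]
    else:
        axis = np.array([1.0, 0.0])
    ang = math.degrees(math.atan2(disp[1], disp[0]) - math.atan2(axis[1], axis[0]))
    ang = (ang + 180.0) % 360.0 - 180.0
    return TakeoffEvent(t_start, t_end, c0, c1, ang, mag)


# ---------------------------------------------------------------------------
# circular statistics


def circular_summary(angles_deg) -> tuple[float, float]:
    """Mean resultant length R-bar = |sum exp(i theta)| / n and circular mean.

    R-bar is 1 when all directions coincide and near 0 for a uniform spread.
    """
    angles = np.asarray(angles_deg, float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    z = np.exp(1j * np.deg2rad(angles)).sum()
    rbar = float(abs(z) / angles.size)
    mean = float(np.rad2deg(np.angle(z))) % 360.0
    return rbar, mean


def hodges_ajne(angles_deg) -> tuple[int, float]:
    """Hodges-Ajne omnibus test of circular uniformity.

    ``m`` is the minimum, over all half-plane boundaries through the origin,
    of the number of sample directions on the emptier side (the boundary is
    scanned just past each data direction, so ties at exact opposition land
    on a side deterministically).  The exact p-value
    ``(n - 2m) C(n, m) / 2^(n-1)`` holds for m < n/3; larger m (an almost
    balanced configuration) is maximally uniform-looking and reports p = 1.
    """
    theta = np.deg2rad(np.asarray(angles_deg, float))
    n = theta.size
    if n < 4:
        raise ValueError("test undefined for n < 4")
    eps = 1e-9
    # candidate boundaries just beside each data direction; the minimum over
    # all half-planes is attained immediately past a data point
    cands = np.concatenate([theta + eps, theta - eps])
    s = np.sin(theta[None, :] - cands[:, None])
    n_pos = (s > 0).sum(axis=1)
    n_neg = (s < 0).sum(axis=1)
    m = int(np.minimum(n_pos, n_neg).min())
    if m >= n / 3:
        return m, 1.0
    p = (n - 2 * m) * math.comb(n, m) / 2 ** (n - 1)
    return m, float(min(1.0, p))


# ---------------------------------------------------------------------------
# postural lean


def t2_leg_angle_series(
    seq: TrackedSequence,
    reference_frame: int = 0,
    butter_order: int = 2,
    cutoff_hz: float = 50.0,
) -> np.ndarray:
    """Delta[T2 leg angle] per frame (degrees), Butterworth-filtered.

    The leg angle is measured between the vertical through the midpoint of
    the two T2 tarsal tips and the segment from that midpoint to the COM
    (side view, x forward, y up); forward lean is positive.  The series is
    reported relative to the pre-stimulus reference frame.
    """
    for label in (COM, T2_LEFT, T2_RIGHT):
        if label not in seq.points:
            raise ValueError(f"sequence lacks {label!r} track")
    mid = (seq.points[T2_LEFT] + seq.points[T2_RIGHT]) / 2
    d = seq.points[COM] - mid
    angle = np.degrees(np.arctan2(d[:, 0], d[:, 1]))  # 0 = COM directly above tarsi
    ref = angle[reference_frame]
    if np.isnan(ref):
        valid = np.flatnonzero(~np.isnan(angle))
        if valid.size == 0:
            return angle
        ref = angle[valid[0]]
    delta = angle - ref

    fs = 1.0 / np.median(np.diff(seq.timestamps))
    if cutoff_hz < fs / 2:
        b, a = butter(butter_order, cutoff_hz / (fs / 2), btype="low")
        out = np.full_like(delta, np.nan)
        # filter each contiguous valid segment separately
        valid = ~np.isnan(delta)
        i = 0
        while i < len(delta):
            if not valid[i]:
                i += 1
                continue
            j = i
            while j < len(delta) and valid[j]:
                j += 1
            seg = delta[i:j]
            padlen = min(3 * (max(len(a), len(b)) - 1), len(seg) - 1)
            out[i:j] = filtfilt(b, a, seg, padlen=padlen) if padlen > 0 else seg
            i = j
        delta = out
    return delta


# ---------------------------------------------------------------------------
# electrophysiology


def _slope_mv_per_ms(trace: EphysTrace) -> np.ndarray:
    """Rise slope: first difference over 1-ms steps, defined at the step start."""
    k = max(1, int(round(trace.rate_khz)))
    v = trace.samples_mv
    slope = np.full(len(v), np.nan)
    slope[: len(v) - k] = v[k:] - v[:-k]
    return slope


def spike_threshold(traces, multiplier: float = 1.0) -> float:
    """Detection threshold: the baseline-region maximum rise slope averaged
    across trials, times ``multiplier``."""
    if isinstance(traces, EphysTrace):
        traces = [traces]
    maxima = []
    for tr in traces:
        sl = _slope_mv_per_ms(tr)[tr.baseline_slice()]
        maxima.append(np.nanmax(sl))
    return multiplier * float(np.mean(maxima))


def detect_spikes(
    trace: EphysTrace,
    threshold_traces=None,
    multiplier: float = 1.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Spike times (ms) in the response region by slope-threshold crossing.

    The slope trace (mV/ms over 1-ms steps) is compared against the
    averaged baseline maximum slope; upward crossings separated by at least
    ``refractory_ms`` are counted as spikes.
    """
    thr = spike_threshold(threshold_traces if threshold_traces is not None else trace, multiplier)
    sl = _slope_mv_per_ms(trace)
    rs = trace.response_slice()
    above = sl[rs] > thr
    idx = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    k = max(1, int(round(trace.rate_khz)))  # report at the end of the 1-ms rise step
    times = (rs.start + idx + k) / trace.rate_khz
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)


def integrated_potential(trace: EphysTrace) -> float:
    """Area (ms x mV) of the baseline-subtracted potential over the 150-ms
    response region (trapezoidal rule)."""
    v = trace.samples_mv
    baseline = float(np.mean(v[trace.baseline_slice()]))
    rs = trace.response_slice()
    seg = v[rs.start : min(rs.stop + 1, len(v))] - baseline
    dt = 1.0 / trace.rate_khz
    return float(np.trapezoid(seg, dx=dt))
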