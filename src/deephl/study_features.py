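"""Downstream behavioral features used to validate attention findings.

These are the species-specific quantities a researcher computes *after* the
network has pointed at interesting segments: open-field behavior classes and
windowed excursion distance for mice, the local trajectory curvature angle
for beetles, the sliding-window dominant frequency of speed for worms, and a
decision-stump information gain to compare candidate per-trajectory features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .trajectory_io import Trajectory

__all__ = [
    "BehaviorSegmentation",
    "segment_mouse_behavior",
    "max_window_distance",
    "circle_crossing_angle",
    "dominant_frequency",
    "information_gain",
]

AMBULATION, IMMOBILITY, FINE_MOVEMENT = "ambulation", "immobility", "fine_movement"


@dataclass
class BehaviorSegmentation:
    """Per-step open-field behavior labels (a partition of the trajectory)."""

    labels: np.ndarray  # of strings, length n

    def mean_speed(self, traj: Trajectory, which: str) -> float:
        """Average step speed (cm/s) over steps labeled ``which``."""
        v = np.hypot(np.diff(traj.x), np.diff(traj.y)) / np.diff(traj.t)
        sel = self.labels[1:] == which
        return float(v[sel].mean()) if sel.any() else float("nan")


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    out, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


def segment_mouse_behavior(traj: Trajectory, units: str = "cm") -> BehaviorSegmentation:
    """Open-field behavior segmentation of a mouse center-point track.

    Ambulation: periods where the center-point velocity, averaged over a
    trailing 0.5 s, exceeds 2 cm/s, sustained for at least 0.5 s.
    Immobility: periods where the displacement over a trailing 1 s stays
    below 1 cm, sustained for at least 1 s.  Everything else is fine
    movement.  Overlaps resolve as immobility > ambulation > fine movement.
    Coordinates must be declared in cm (timestamps in s).
    """
    if units != "cm":
        raise ValidationError(f"mouse segmentation requires cm coordinates, got {units!r}")
    traj.validate()
    t = traj.t
    n = len(t)
    path = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(traj.x), np.diff(traj.y)))])
    # trailing windows (shrunk at the start): average speed over 0.5 s,
    # accumulated path change over 1 s
    avg_speed = np.zeros(n)
    change_1s = np.zeros(n)
    j05 = j10 = 0
    for i in range(n):
        while t[i] - t[j05] > 0.5:
            j05 += 1
        while t[i] - t[j10] > 1.0:
            j10 += 1
        if t[i] > t[j05]:
            avg_speed[i] = (path[i] - path[j05]) / (t[i] - t[j05])
        change_1s[i] = path[i] - path[j10]
    if n > 1:
        avg_speed[0] = avg_speed[1]  # point 0 has no trailing window

    amb_flag = avg_speed > 2.0
    imm_flag = change_1s < 1.0
    labels = np.array([FINE_MOVEMENT] * n, dtype=object)
    for lo, hi in _runs(amb_flag):
        if t[hi - 1] - t[lo] >= 0.5 - 1e-12:
            labels[lo:hi] = AMBULATION
    for lo, hi in _runs(imm_flag):
        if t[hi - 1] - t[lo] >= 1.0 - 1e-12:
            labels[lo:hi] = IMMOBILITY  # immobility takes precedence
    return BehaviorSegmentation(labels=labels)


def max_window_distance(traj: Trajectory, half_window: float = 60.0):
    """Largest straight-line excursion from each point within +/- ``half_window`` s.

    For every point p_i, the maximum Euclidean distance between p_i (the
    window center) and any point whose timestamp lies within the window (the
    window shrinks at the edges).  Returns ``(series, trajectory_max)``.
    """
    traj.validate()
    t, p = traj.t, traj.points()
    n = len(t)
    series = np.zeros(n)
    lo = hi = 0
    for i in range(n):
        while t[i] - t[lo] > half_window:
            lo += 1
        while hi < n and t[hi] - t[i] <= half_window:
            hi += 1
        d = np.hypot(p[lo:hi, 0] - p[i, 0], p[lo:hi, 1] - p[i, 1])
        series[i] = d.max()
    return series, float(series.max())


def _first_crossing(p: np.ndarray, center: np.ndarray, idx: range, r: float):
    """First point along ``idx`` where the track crosses distance r from
    ``center``, linearly interpolated between the straddling samples."""
    prev = None
    for j in idx:
        d = float(np.hypot(*(p[j] - center)))
        if d >= r:
            if prev is None:
                return p[j]  # first sample already beyond the circle
            jp, dp = prev
            frac = (r - dp) / (d - dp) if d != dp else 1.0
            return p[jp] + frac * (p[j] - p[jp])
        prev = (j, d)
    return None


def circle_crossing_angle(traj: Trajectory, r: float = 100.0):
    """Local curvature angle at each point (beetle turning analysis).

    A circle of radius ``r`` (default 100 mm) is centered at each point p;
    n and m are where the track first crosses the circle going backward and
    forward in time (linear interpolation between samples).  The returned
    angle at p is the angle between p->n and p->m, in [0, pi]; points where
    either crossing does not exist are NaN.  Returns ``(angles, n_defined)``.
    """
    traj.validate()
    p = traj.points()
    n = len(p)
    angles = np.full(n, np.nan)
    for i in range(n):
        back = _first_crossing(p, p[i], range(i - 1, -1, -1), r)
        fwd = _first_crossing(p, p[i], range(i + 1, n), r)
        if back is None or fwd is None:
            continue
        u, v = back - p[i], fwd - p[i]
        nu, nv = np.hypot(*u), np.hypot(*v)
        if nu == 0 or nv == 0:
            continue
        angles[i] = np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return angles, int(np.isfinite(angles).sum())


def dominant_frequency(speed_series: np.ndarray, rate: float = 1.0,
                       window: float = 128.0):
    """Sliding-window dominant frequency of a speed series.

    A ``window``-second window (``window * rate`` samples) slides in 1-sample
    steps; in each window the FFT amplitude spectrum is computed and the
    frequency bin with the largest amplitude — excluding DC — is reported.
    Returns ``(frequencies, amplitudes)``; a zero amplitude marks windows
    with no oscillatory content (the lowest nonzero bin is then reported).
    """
    x = np.asarray(speed_series, dtype=float)
    w = int(round(window * rate))
    if len(x) < w:
        raise ValidationError(f"series length {len(x)} shorter than window ({w} samples)")
    n_win = len(x) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    amp = np.abs(np.fft.rfft(windows, axis=1))
    amp = amp[:, 1:]  # exclude DC
    k = amp.argmax(axis=1) + 1
    freqs = k * rate / w
    peak = amp.max(axis=1)
    freqs = np.where(peak == 0.0, rate / w, freqs)
    return freqs, peak


def information_gain(feature_values: np.ndarray, labels: np.ndarray) -> float:
    """Information gain (bits) of the best single-threshold split.

    H(labels) minus the minimum weighted child entropy over all thresholds
    midway between consecutive sorted unique feature values — i.e. the gain
    of the optimal decision stump.  A constant feature yields 0.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    if len(x) != len(y) or len(x) == 0:
        raise ValidationError("feature values and labels must be equal-length, nonempty")

    def entropy(v) -> float:
        if len(v) == 0:
            return 0.0
        _, counts = np.unique(v, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h0 = entropy(y)
    uniq = np.unique(x)
    if len(uniq) < 2:
        return 0.0
    best = h0
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(x)
    for thr in thresholds:
        left = x <= thr
        h = (left.sum() / n) * entropy(y[left]) + ((~left).sum() / n) * entropy(y[~left])
        best = min(best, h)
    return h0 - best
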