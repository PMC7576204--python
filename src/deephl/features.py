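"""Primitive and handcrafted movement features, and network input tensors.

The classifier consumes position- and rotation-invariant primitive features
(speed, relative angular speed); interpretation additionally uses the travel
distance from the start, the straight-line distance from the start and the
angle between the +y axis and the vector from the start, plus moving
statistics of any of these.

Channel alignment: speed loses one sample and relative angular speed two, so
every channel is truncated to the common derived length ``n - 2`` (the first
two raw samples are dropped).  Row ``k`` of every channel then refers to
trajectory point ``k + 2``, which keeps attention indexing exact.

Standardization is dataset-global: each channel is z-scored with the mean/SD
pooled over the valid steps of *all* trajectories, preserving
between-trajectory magnitude differences.  Tensors are padded to ``l_max``
with the sentinel value -1.0 and carry a boolean validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajectory_io import Trajectory

__all__ = [
    "speed",
    "relative_angular_speed",
    "travel_distance",
    "straight_line_distance_from_origin",
    "angle_from_origin",
    "moving_stats",
    "FeatureTensor",
    "FeatureSeriesSet",
    "FeatureBundle",
    "build_feature_tensor",
    "save_tensors",
    "load_tensors",
    "SENTINEL",
    "DEFAULT_CHANNELS",
    "ALL_CHANNELS",
]

SENTINEL = -1.0
DEFAULT_CHANNELS = ("speed", "angular_speed")
ALL_CHANNELS = ("speed", "angular_speed", "travel_distance",
                "distance_from_origin", "angle_from_origin")
#: default centered window (steps) for moving statistics
DEFAULT_WINDOW = 21


def speed(traj: Trajectory) -> np.ndarray:
    """Step speed ||p_i - p_{i-1}|| / dt_i; length n - 1."""
    if len(traj) < 2:
        raise ValidationError(f"trajectory {traj.id}: speed needs >= 2 points")
    dt = np.diff(traj.t)
    if np.any(dt == 0):
        raise ValidationError(f"trajectory {traj.id}: zero time step")
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return d / dt


def _headings(traj: Trajectory) -> np.ndarray:
    """Heading of each step; zero-length steps carry the last nonzero heading
    forward (leading zero-length steps get heading 0)."""
    dx, dy = np.diff(traj.x), np.diff(traj.y)
    theta = np.arctan2(dy, dx)
    moved = (dx != 0) | (dy != 0)
    if not moved.all():
        theta = theta.copy()
        last = 0.0
        for i in range(len(theta)):
            if moved[i]:
                last = theta[i]
            else:
                theta[i] = last
    return theta


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap into (-pi, pi]."""
    return np.pi - np.mod(np.pi - angle, 2.0 * np.pi)


def relative_angular_speed(traj: Trajectory) -> np.ndarray:
    """Heading change per unit time, wrapped into (-pi, pi]; length n - 2."""
    if len(traj) < 3:
        raise ValidationError(f"trajectory {traj.id}: angular speed needs >= 3 points")
    theta = _headings(traj)
    dt = np.diff(traj.t)[1:]
    return _wrap(np.diff(theta)) / dt


def travel_distance(traj: Trajectory) -> np.ndarray:
    """Cumulative path length at each point; length n (0 at the start)."""
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return np.concatenate([[0.0], np.cumsum(d)])


def straight_line_distance_from_origin(traj: Trajectory) -> np.ndarray:
    """Euclidean distance from the initial position; length n."""
    return np.hypot(traj.x - traj.x[0], traj.y - traj.y[0])


def angle_from_origin(traj: Trajectory) -> np.ndarray:
    """Unsigned angle in [0, pi] between the +y axis and p_i - p_0; length n.

    The initial point (zero displacement) is assigned angle 0.
    """
    dx, dy = traj.x - traj.x[0], traj.y - traj.y[0]
    r = np.hypot(dx, dy)
    ang = np.zeros(len(traj))
    nz = r > 0
    ang[nz] = np.arccos(np.clip(dy[nz] / r[nz], -1.0, 1.0))
    return ang


def moving_stats(series: np.ndarray, window: int = DEFAULT_WINDOW, dt: float = 1.0):
    """Centered moving average/variance (window shrinks at the edges) and the
    first-difference derivative of a series.

    Returns ``(moving_average, moving_variance, derivative)``, all the same
    length as the input; the derivative's first element is 0.  Variance is
    the population variance within each window.
    """
    series = np.asarray(series, dtype=float)
    if window < 2 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 3")
    if window > len(series):
        raise ValidationError(f"window {window} exceeds series length {len(series)}")
    s = pd.Series(series)
    roll = s.rolling(window, center=True, min_periods=1)
    mavg = roll.mean().to_numpy()
    mvar = roll.var(ddof=0).to_numpy()
    deriv = np.concatenate([[0.0], np.diff(series) / dt])
    return mavg, mvar, deriv


_CHANNEL_FUNCS = {
    "speed": speed,
    "angular_speed": relative_angular_speed,
    "travel_distance": travel_distance,
    "distance_from_origin": straight_line_distance_from_origin,
    "angle_from_origin": angle_from_origin,
}


def raw_channel(traj: Trajectory, name: str) -> np.ndarray:
    """One aligned (length n - 2) raw feature or extra-sensor channel."""
    if name in _CHANNEL_FUNCS:
        full = _CHANNEL_FUNCS[name](traj)
    elif name in traj.extras:
        full = np.asarray(traj.extras[name], dtype=float)
    else:
        raise ValidationError(f"trajectory {traj.id}: unknown channel {name!r}")
    want = len(traj) - 2
    return full[len(full) - want:]


@dataclass
class FeatureTensor:
    """Standardized multichannel input for one trajectory, padded to l_max."""

    trajectory_id: str
    label: str
    values: np.ndarray  # (l_max, n_channels); padded cells hold SENTINEL
    mask: np.ndarray  # (l_max,) bool
    channel_names: tuple

    @property
    def valid_length(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureSeriesSet:
    """Raw (unstandardized) aligned feature series, for correlation and
    distribution-difference analyses."""

    series: dict  # trajectory_id -> {channel -> ndarray}
    labels: dict  # trajectory_id -> label
    channel_names: tuple
    dt: dict  # trajectory_id -> median time step

    def by_class(self, channel: str) -> dict:
        out: dict[str, list[np.ndarray]] = {}
        for tid, chans in self.series.items():
            out.setdefault(self.labels[tid], []).append(chans[channel])
        return out


@dataclass
class FeatureBundle:
    tensors: list  # of FeatureTensor, dataset order
    series_set: FeatureSeriesSet
    channel_means: np.ndarray
    channel_sds: np.ndarray
    l_max: int
    channel_names: tuple


def build_feature_tensor(trajectories: list[Trajectory],
                         channels: tuple = DEFAULT_CHANNELS,
                         l_max: int | None = None,
                         stats: tuple[np.ndarray, np.ndarray] | None = None) -> FeatureBundle:
    """Build standardized, padded input tensors for a dataset.

    ``stats`` may carry (means, sds) frozen from a training run so that new
    data is standardized identically; otherwise dataset-global statistics are
    computed here.  A channel with zero dataset-wide SD is rejected.
    """
    channels = tuple(channels)
    if len(channels) < 2:
        raise ValidationError("at least two feature channels are required")
    # raw copies of the selected channels (plus extra sensor channels shared
    # by all trajectories) are kept for correlation / distribution analyses
    extras_common = set.intersection(*(set(tr.extras) for tr in trajectories)) \
        if trajectories else set()
    corr_channels = tuple(dict.fromkeys(channels + tuple(sorted(extras_common))))
    raw = {tr.id: {ch: raw_channel(tr, ch) for ch in corr_channels} for tr in trajectories}
    labels = {tr.id: tr.label for tr in trajectories}
    dts = {tr.id: float(np.median(np.diff(tr.t))) for tr in trajectories}
    lengths = [len(tr) - 2 for tr in trajectories]
    if l_max is None:
        l_max = max(lengths)
    if stats is None:
        means = np.array([np.mean(np.concatenate([raw[t.id][ch] for t in trajectories]))
                          for ch in channels])
        sds = np.array([np.std(np.concatenate([raw[t.id][ch] for t in trajectories]))
                        for ch in channels])
        for ch, sd in zip(channels, sds):
            if sd == 0:
                raise ValidationError(f"channel {ch!r} has zero dataset-wide SD")
    else:
        means, sds = np.asarray(stats[0]), np.asarray(stats[1])
    tensors = []
    for tr, n in zip(trajectories, lengths):
        vals = np.full((l_max, len(channels)), SENTINEL)
        mask = np.zeros(l_max, dtype=bool)
        if n > l_max:
            raise ValidationError(f"trajectory {tr.id} longer than l_max={l_max}")
        for j, ch in enumerate(channels):
            vals[:n, j] = (raw[tr.id][ch] - means[j]) / sds[j]
        mask[:n] = True
        tensors.append(FeatureTensor(tr.id, tr.label, vals, mask, channels))
    series_set = FeatureSeriesSet(series=raw, labels=labels, channel_names=corr_channels, dt=dts)
    return FeatureBundle(tensors, series_set, means, sds, l_max, channels)


def save_tensors(bundle: FeatureBundle, path) -> None:
    """Cache a feature bundle's tensors to an HDF5 sidecar."""
    with h5py.File(path, "w") as f:
        f.attrs["channels"] = list(bundle.channel_names)
        f.attrs["l_max"] = bundle.l_max
        f.create_dataset("means", data=bundle.channel_means)
        f.create_dataset("sds", data=bundle.channel_sds)
        for ft in bundle.tensors:
            g = f.create_group(ft.trajectory_id)
            g.attrs["label"] = ft.label
            g.create_dataset("values", data=ft.values)
            g.create_dataset("mask", data=ft.mask)


def load_tensors(path) -> tuple[list[FeatureTensor], np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        channels = tuple(f.attrs["channels"])
        tensors = [FeatureTensor(tid, f[tid].attrs["label"],
                                 f[tid]["values"][...], f[tid]["mask"][...].astype(bool),
                                 channels)
                   for tid in f if isinstance(f[tid], h5py.Group)]
        return tensors, f["means"][...], f["sds"][...]
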