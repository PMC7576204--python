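"""Synthetic two-class trajectory generator with planted group differences.

Trajectories follow a two-state semi-Markov correlated random walk that mimics
the run/pirouette structure of nematode locomotion: a *run* state with steady
speed and a small turning-angle SD alternating with a *turn* state with low
speed and a large turning-angle SD.  Dwell times in each state are geometric.

Class B trajectories carry a planted, localized effect:

- ``speed_burst``: selected run bouts have their per-step speed multiplied by
  ``effect_magnitude`` (class B animals sprint during some runs);
- ``sharp_turn``: selected turn bouts have their turning-angle SD multiplied
  by ``effect_magnitude`` (class B reorients more violently);
- ``origin_drift``: one contiguous window gains a slow constant drift away
  from the origin (mimics a distance-from-start signature).

Every trajectory is emitted together with a boolean ground-truth mask marking
the planted steps, so attention-recovery can be scored exactly.  Class A masks
are all false.  Generation is reproducible: each trajectory uses an
independent substream keyed by ``(seed, trajectory counter)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trajectory_io import Trajectory, write_dataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "save_dataset"]

EFFECTS = ("speed_burst", "sharp_turn", "origin_drift")

#: speed in the turn state as a fraction of run_speed_mean
TURN_SPEED_FRACTION = 0.3
#: per-step multiplicative speed noise (SD as a fraction of the state mean)
SPEED_CV = 0.25
#: probability that an eligible bout carries the planted effect in class B
PLANT_PROB = 0.5
#: origin_drift: window covers this fraction of the trajectory ...
DRIFT_WINDOW_FRACTION = 0.3
#: ... and drifts at this fraction of run_speed_mean per unit magnitude
DRIFT_SPEED_FRACTION = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-state correlated-random-walk generator."""

    n_per_class: int = 100
    traj_len: int = 200
    dt: float = 1.0
    state_dwell_mean: dict = field(default_factory=lambda: {"run": 20.0, "turn": 5.0})
    run_speed_mean: float = 1.0
    turn_rate_sd: dict = field(default_factory=lambda: {"run": 0.1, "turn": 1.0})
    effect: str = "speed_burst"
    effect_magnitude: float = 3.0
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.effect not in EFFECTS:
            raise ConfigurationError(f"unknown effect {self.effect!r}; choose from {EFFECTS}")
        if self.n_per_class < 2:
            raise ConfigurationError("n_per_class must be >= 2")
        if self.traj_len < 20:
            raise ConfigurationError("traj_len must be >= 20")
        if any(v < 1 for v in self.state_dwell_mean.values()):
            raise ConfigurationError("state dwell means must be >= 1 step")
        if self.traj_len < max(self.state_dwell_mean.values()):
            raise ConfigurationError("traj_len shorter than the longest mean dwell")
        if self.effect_magnitude <= 0:
            raise ConfigurationError("effect_magnitude must be > 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one trajectory: planted-segment mask and label."""

    trajectory_id: str
    label: str
    mask: np.ndarray  # bool, length traj_len


def _state_sequence(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """0 = run, 1 = turn; geometric dwell times, starting in run."""
    states = np.empty(cfg.traj_len, dtype=np.int8)
    pos, state = 0, 0
    while pos < cfg.traj_len:
        mean = cfg.state_dwell_mean["run" if state == 0 else "turn"]
        dwell = rng.geometric(1.0 / mean)
        states[pos:pos + dwell] = state
        pos += dwell
        state = 1 - state
    return states


def _bouts(states: np.ndarray, which: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of the given state."""
    out, start = [], None
    for i, s in enumerate(states):
        if s == which and start is None:
            start = i
        elif s != which and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(states)))
    return out


def _plant_mask(rng: np.random.Generator, cfg: SyntheticConfig, states: np.ndarray) -> np.ndarray:
    mask = np.zeros(cfg.traj_len, dtype=bool)
    if cfg.effect == "origin_drift":
        w = max(1, round(DRIFT_WINDOW_FRACTION * cfg.traj_len))
        start = int(rng.integers(0, cfg.traj_len - w + 1))
        mask[start:start + w] = True
        return mask
    target_state = 0 if cfg.effect == "speed_burst" else 1
    bouts = _bouts(states, target_state)
    if not bouts:
        return mask  # degenerate dwell draw; caller leaves this trajectory unaffected
    chosen = [b for b in bouts if rng.random() < PLANT_PROB]
    if not chosen:
        chosen = [bouts[int(rng.integers(len(bouts)))]]
    for lo, hi in chosen:
        mask[lo:hi] = True
    return mask


def _simulate_one(rng: np.random.Generator, cfg: SyntheticConfig, planted: bool):
    states = _state_sequence(rng, cfg)
    mask = _plant_mask(rng, cfg, states) if planted else np.zeros(cfg.traj_len, dtype=bool)

    speed_mean = np.where(states == 0, cfg.run_speed_mean,
                          TURN_SPEED_FRACTION * cfg.run_speed_mean)
    speeds = np.maximum(0.0, speed_mean * (1.0 + SPEED_CV * rng.standard_normal(cfg.traj_len)))
    turn_sd = np.where(states == 0, cfg.turn_rate_sd["run"], cfg.turn_rate_sd["turn"])
    if planted and cfg.effect == "speed_burst":
        speeds = np.where(mask, speeds * cfg.effect_magnitude, speeds)
    if planted and cfg.effect == "sharp_turn":
        turn_sd = np.where(mask, turn_sd * cfg.effect_magnitude, turn_sd)

    headings = np.cumsum(turn_sd * rng.standard_normal(cfg.traj_len))
    headings += rng.uniform(0.0, 2.0 * np.pi)  # random initial bearing
    steps = speeds[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    if planted and cfg.effect == "origin_drift":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        drift = DRIFT_SPEED_FRACTION * cfg.effect_magnitude * cfg.run_speed_mean
        steps[mask] += drift * np.array([np.cos(phi), np.sin(phi)])
    xy = np.cumsum(steps, axis=0)
    xy += cfg.noise_sd * rng.standard_normal(xy.shape)

    log = {"states": states, "speeds": speeds, "turn_sd": turn_sd, "headings": headings}
    return xy, mask, log


def generate_dataset(config: SyntheticConfig, return_state_logs: bool = False):
    """Generate ``2 * n_per_class`` labeled trajectories plus ground truth.

    Returns ``(trajectories, truths)`` or, with ``return_state_logs=True``,
    ``(trajectories, truths, logs)`` where each log records the internal state
    sequence and pre-noise step speeds (the oracle for segment-level tests).
    """
    config.validate()
    trajectories: list[Trajectory] = []
    truths: list[SyntheticTruth] = []
    logs: list[dict] = []
    t = np.arange(config.traj_len) * config.dt
    counter = 0
    for label, planted in (("A", False), ("B", True)):
        for k in range(config.n_per_class):
            rng = np.random.default_rng([config.seed, counter])
            xy, mask, log = _simulate_one(rng, config, planted)
            tid = f"{label}{k:04d}"
            trajectories.append(Trajectory(id=tid, t=t.copy(), x=xy[:, 0], y=xy[:, 1],
                                           extras={}, label=label))
            truths.append(SyntheticTruth(trajectory_id=tid, label=label, mask=mask))
            logs.append(log)
            counter += 1
    if return_state_logs:
        return trajectories, truths, logs
    return trajectories, truths


def save_dataset(trajectories: list[Trajectory], truths: list[SyntheticTruth],
                 out_dir: str | Path) -> Path:
    """Write trajectory CSVs + manifest plus a truth-mask sidecar CSV.

    Returns the manifest path.  The sidecar ``truth_masks.csv`` has columns
    (trajectory_id, t_index, in_segment).
    """
    out_dir = Path(out_dir)
    manifest = write_dataset(trajectories, out_dir)
    rows = [(tr.trajectory_id, i, int(v))
            for tr in truths for i, v in enumerate(tr.mask)]
    pd.DataFrame(rows, columns=["trajectory_id", "t_index", "in_segment"]).to_csv(
        out_dir / "truth_masks.csv", index=False)
    return manifest


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """The same conditions with the effect switched off (magnitude 1)."""
    return replace(config, effect_magnitude=1.0)
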