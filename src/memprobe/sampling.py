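"""Snapshot selection for ensemble spectra.

Implements the hierarchical sampling protocol used for emission ensembles:
from a long excited-state trajectory, take n_secondary equidistant snapshots
(e.g. 22 from the final 50 ns); each seeds a short secondary (polarizable)
trajectory, from which n_sub equidistant sub-snapshots are taken inside a
sub-window (e.g. 10 between 1 and 2 ns) — 22 x 10 = 220 geometries per
bilayer.  Absorption ensembles use plain equidistant or uniform-random
selection over a window.

Equidistant selection is endpoint-inclusive with (n-1) equal intervals;
n = 1 picks the window midpoint.  Requested times snap to the nearest stored
frame, ties resolving to the earlier frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SamplingPlan",
    "TrajectoryIndex",
    "EnsembleManifest",
    "equidistant_times",
    "equidistant_snapshots",
    "random_snapshots",
    "emission_protocol",
]


class WindowError(ValueError):
    """A sampling window does not fit the trajectory or the request size."""


@dataclass
class SamplingPlan:
    t_start_ns: float
    t_end_ns: float
    n_snapshots: int
    mode: str = "equidistant"  # or "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_start_ns >= self.t_end_ns:
            raise ValueError("t_start must precede t_end")
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.mode not in ("equidistant", "random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "random" and self.seed is None:
            raise ValueError("random mode requires a seed")


@dataclass
class TrajectoryIndex:
    """Bookkeeping view of a stored trajectory: its id and frame times (ns)."""

    trajectory_id: str
    times_ns: np.ndarray
    paths: list[str] | None = None

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if len(self.times_ns) == 0:
            raise ValueError("trajectory has no frames")
        if np.any(np.diff(self.times_ns) < 0):
            raise ValueError("frame times must be non-decreasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times_ns[0]), float(self.times_ns[-1])


@dataclass
class EnsembleManifest:
    """Selected snapshots: one row per (trajectory, time), with protocol stage."""

    entries: pd.DataFrame  # stage, trajectory_id, time_ns, frame_index, path
    stage: str

    def __post_init__(self) -> None:
        dup = self.entries.duplicated(subset=["trajectory_id", "time_ns"])
        if dup.any():
            raise ValueError("manifest entries must be unique by (trajectory, time)")

    def __len__(self) -> int:
        return len(self.entries)

    def write_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def equidistant_times(t_start: float, t_end: float, n: int) -> np.ndarray:
    """Endpoint-inclusive equidistant times; a single snapshot takes the midpoint."""
    if n == 1:
        return np.array([0.5 * (t_start + t_end)])
    return t_start + (t_end - t_start) * np.arange(n) / (n - 1)


def _snap_to_frames(times: np.ndarray, stored: np.ndarray) -> np.ndarray:
    """Nearest stored-frame index for each requested time; ties -> earlier frame."""
    idx = np.empty(len(times), dtype=int)
    for k, t in enumerate(times):
        d = np.abs(stored - t)
        idx[k] = int(np.argmin(d))  # argmin returns the first (earlier) minimum
    return idx


def _check_window(traj: TrajectoryIndex, t0: float, t1: float) -> None:
    lo, hi = traj.span
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise WindowError(
            f"window [{t0}, {t1}] ns outside trajectory span [{lo}, {hi}] ns"
        )


def _manifest(traj: TrajectoryIndex, frame_idx: np.ndarray, stage: str) -> EnsembleManifest:
    entries = pd.DataFrame(
        {
            "stage": stage,
            "trajectory_id": traj.trajectory_id,
            "time_ns": traj.times_ns[frame_idx],
            "frame_index": frame_idx,
            "path": [traj.paths[i] if traj.paths else "" for i in frame_idx],
        }
    )
    return EnsembleManifest(entries=entries, stage=stage)


def equidistant_snapshots(
    traj: TrajectoryIndex, plan: SamplingPlan, stage: str = "absorption-primary"
) -> EnsembleManifest:
    if plan.mode != "equidistant":
        raise ValueError("plan mode must be 'equidistant'")
    _check_window(traj, plan.t_start_ns, plan.t_end_ns)
    times = equidistant_times(plan.t_start_ns, plan.t_end_ns, plan.n_snapshots)
    return _manifest(traj, _snap_to_frames(times, traj.times_ns), stage)


def random_snapshots(
    traj: TrajectoryIndex, plan: SamplingPlan, stage: str = "absorption-random"
) -> EnsembleManifest:
    """Uniform draw of ``n_snapshots`` distinct frames inside the window."""
    if plan.mode != "random":
        raise ValueError("plan mode must be 'random'")
    _check_window(traj, plan.t_start_ns, plan.t_end_ns)
    in_window = np.flatnonzero(
        (traj.times_ns >= plan.t_start_ns - 1e-9) & (traj.times_ns <= plan.t_end_ns + 1e-9)
    )
    if plan.n_snapshots > len(in_window):
        raise WindowError(
            f"requested {plan.n_snapshots} snapshots but only {len(in_window)} frames in window"
        )
    rng = np.random.default_rng(plan.seed)
    chosen = np.sort(rng.choice(in_window, size=plan.n_snapshots, replace=False))
    return _manifest(traj, chosen, stage)


def emission_protocol(
    primary: TrajectoryIndex,
    primary_window: tuple[float, float],
    n_secondary: int = 22,
    secondary_length_ns: float = 2.0,
    sub_window: tuple[float, float] = (1.0, 2.0),
    n_sub: int = 10,
) -> EnsembleManifest:
    """Hierarchical emission sampling: primary seeds -> secondary sub-snapshots.

    ``n_secondary`` equidistant seeds are taken from ``primary_window`` of the
    primary trajectory; each labels a secondary trajectory of length
    ``secondary_length_ns`` from which ``n_sub`` equidistant times inside
    ``sub_window`` (relative to the secondary start) are emitted.  The
    manifest holds the n_secondary x n_sub sub-snapshots; secondary dynamics
    itself is an input, not something this function runs.

    With the defaults (22 seeds from 50 ns, 10 sub-snapshots in [1, 2] ns)
    the manifest has 220 entries.
    """
    if n_secondary < 1 or n_sub < 1:
        raise ValueError("counts must be positive")
    if not (0.0 <= sub_window[0] < sub_window[1] <= secondary_length_ns + 1e-9):
        raise WindowError(
            f"sub-window {sub_window} must lie inside the {secondary_length_ns} ns secondary run"
        )
    _check_window(primary, *primary_window)
    seed_times = equidistant_times(*primary_window, n_secondary)
    seed_idx = _snap_to_frames(seed_times, primary.times_ns)
    sub_times = equidistant_times(sub_window[0], sub_window[1], n_sub)

    rows = []
    for j, si in enumerate(seed_idx):
        sec_id = f"{primary.trajectory_id}/sec{j:02d}"
        seed_t = primary.times_ns[si]
        for t in sub_times:
            rows.append(
                {
                    "stage": "emission-secondary",
                    "trajectory_id": sec_id,
                    "time_ns": float(t),
                    "frame_index": -1,  # secondary frames live outside the primary store
                    "path": "",
                    "seed_time_ns": float(seed_t),
                    "seed_frame_index": int(si),
                }
            )
    return EnsembleManifest(entries=pd.DataFrame(rows), stage="emission-secondary")
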