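"""In-memory containers: COP trajectories, force recordings, trial sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CopTrajectory", "ForceRecording", "TrialSet", "as_force_array"]

N_SENSORS = 12


@dataclass
class CopTrajectory:
    """A time series of COP positions in the insole frame (mm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("COP trajectory contains non-finite values")

    def __len__(self) -> int:
        return self.t.size

    def axis(self, name: str) -> np.ndarray:
        """Return the 'ml' (x) or 'ap' (y) component."""
        if name in ("ml", "x"):
            return self.x
        if name in ("ap", "y"):
            return self.y
        raise ValueError(f"unknown axis {name!r}; use 'ml' or 'ap'")

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class ForceRecording:
    """A 12-channel force series, optionally paired with a reference COP.

    ``forces`` is (m, 12) in newtons, column i holding sensor i+1. The total
    force is always recomputed from the channels (never stored), so the
    row-sum identity of the design matrix holds by construction.
    """

    t: np.ndarray
    forces: np.ndarray
    ref: CopTrajectory | None = None
    fs: float = 50.0
    subject: str = "S00"
    foot: str = "left"
    task: int = 1
    trial: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != N_SENSORS:
            raise ValueError(
                f"forces must be (m, {N_SENSORS}), got {self.forces.shape}"
            )
        if self.t.shape != (self.forces.shape[0],):
            raise ValueError("t length does not match number of force frames")
        if np.any(self.forces < 0):
            raise ValueError("negative force value; channel forces must be >= 0 N")
        if self.ref is not None and len(self.ref) != self.forces.shape[0]:
            raise ValueError("reference COP length does not match force series")

    def __len__(self) -> int:
        return self.forces.shape[0]

    @property
    def f_tot(self) -> np.ndarray:
        """Total force per frame (N), recomputed as the exact channel sum."""
        return self.forces.sum(axis=1)


@dataclass
class TrialSet:
    """All recordings of one subject-foot: tasks x trials, shared rate."""

    recordings: list[ForceRecording]

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("TrialSet needs at least one recording")
        keys = [(r.subject, r.foot) for r in self.recordings]
        if len(set(keys)) != 1:
            raise ValueError(f"TrialSet spans several subject-feet: {sorted(set(keys))}")
        fss = {r.fs for r in self.recordings}
        if len(fss) != 1:
            raise ValueError(f"recordings do not share a sampling rate: {sorted(fss)}")
        seen = set()
        for r in self.recordings:
            key = (r.task, r.trial)
            if key in seen:
                raise ValueError(f"duplicate (task, trial) combination {key}")
            seen.add(key)

    @property
    def subject(self) -> str:
        return self.recordings[0].subject

    @property
    def foot(self) -> str:
        return self.recordings[0].foot

    @property
    def fs(self) -> float:
        return self.recordings[0].fs

    @property
    def tasks(self) -> list[int]:
        return sorted({r.task for r in self.recordings})

    @property
    def trials(self) -> list[int]:
        return sorted({r.trial for r in self.recordings})


def as_force_array(frames) -> np.ndarray:
    """Coerce a ForceRecording or array-like into an (m, 12) force array."""
    if isinstance(frames, ForceRecording):
        return frames.forces
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] != N_SENSORS:
        raise ValueError(f"expected an (m, {N_SENSORS}) force array, got {arr.shape}")
    return arr
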