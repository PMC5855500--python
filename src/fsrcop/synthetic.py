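"""Synthetic plantar-pressure recordings with analytic ground-truth COP.

The simulator represents the plantar load as a mixture of K = 9 pressure
blobs pinned to anatomical loci (heel, midfoot, the five metatarsal heads,
great toe, lesser toes). Per frame, non-negative blob amplitudes A_k(t)
sum to the prescribed total load L(t), and the ground-truth COP is the
amplitude-weighted centroid of the loci:

    cop(t) = sum_k A_k(t) r_k / sum_k A_k(t).

Given a target COP path and load profile, amplitudes are recovered by
exponential tilting of a baseline load-share vector: A_k proportional to
w_k exp(theta(t) . r_k), with the 2-vector theta(t) solved per frame by a
damped Newton iteration on the centroid-matching condition. Tilting keeps
amplitudes strictly positive and is exact for any target COP strictly
inside the convex hull of the loci; target paths are clamped to an inset
hull before solving.

Sensor forward model: each blob's load is apportioned across the twelve
FSR positions by Gaussian proximity weights normalised to sum to one per
blob (the sensor array registers the full regional load). A subject
profile then applies individual-specific imperfections: per-sensor
multiplicative gains, placement offsets of the physical sensors relative
to the nominal layout, a compressive response exponent, additive Gaussian
noise, and 10-bit quantisation of the acquisition chain.

Task battery (one recording per task x trial):

1. quiet standing, eyes open  (10 s)     4. sit-down, with armrests (5 s)
2. quiet standing, eyes closed (10 s)    5. stand-up, no armrests   (5 s)
3. stand-up, with armrests     (5 s)     6. sit-down, no armrests   (5 s)

Quiet-standing sway is second-order low-pass filtered white noise (1 Hz
cutoff) rescaled so the realised per-axis COP range and mean hit the
task targets; transitions superpose a deterministic load ramp and an
anterior COP excursion, with armrest variants reaching a lower seat-off
peak load than armrest-free ones. Per-trial targets are drawn around the
task defaults, so target ranges are inputs, not predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt
from scipy.spatial import ConvexHull
from shapely import contains_xy
from shapely.geometry import Point, Polygon

from .geometry import SensorLayout, default_layout
from .recording import CopTrajectory, ForceRecording, TrialSet

__all__ = [
    "SubjectProfile",
    "PressureScene",
    "TaskTarget",
    "CohortConfig",
    "TASK_TARGETS",
    "ANATOMICAL_LOCI",
    "simulate_task",
    "sample_sensors",
    "make_cohort",
    "solve_blob_amplitudes",
]

FS_DEFAULT = 50.0

# Anatomical loci (mm, insole frame): name -> (x, y)
ANATOMICAL_LOCI: dict[str, tuple[float, float]] = {
    "heel": (50.0, 30.0),
    "midfoot": (55.0, 105.0),
    "mt1": (25.0, 185.0),
    "mt2": (42.0, 195.0),
    "mt3": (54.0, 193.0),
    "mt4": (66.0, 185.0),
    "mt5": (82.0, 172.0),
    "great_toe": (32.0, 255.0),
    "lesser_toes": (68.0, 242.0),
}

# Baseline quiet-standing load shares per locus (sum to 1).
_BASE_WEIGHTS = np.array([0.22, 0.08, 0.12, 0.11, 0.10, 0.08, 0.06, 0.13, 0.10])

_HULL_MARGIN = 5.0  # mm inset of the admissible-COP hull
_KERNEL_SIGMA = 25.0  # mm, Gaussian footprint of a blob over the sensor grid


@dataclass(frozen=True)
class TaskTarget:
    """Per-task COP range/mean targets (mm) and trial morphology."""

    task: int
    name: str
    kind: str  # "quiet" | "rise" | "sit"
    armrest: bool | None
    duration: float  # s
    ml_range: float
    ml_range_sd: float
    ap_range: float
    ap_range_sd: float
    ml_mean: float
    ml_mean_sd: float
    ap_mean: float
    ap_mean_sd: float


TASK_TARGETS: dict[int, TaskTarget] = {
    1: TaskTarget(1, "quiet standing, eyes open", "quiet", None, 10.0,
                  2.5, 0.3, 6.9, 2.5, 42.4, 1.4, 189.8, 2.6),
    2: TaskTarget(2, "quiet standing, eyes closed", "quiet", None, 10.0,
                  8.7, 1.2, 16.4, 3.0, 45.2, 7.2, 193.9, 1.6),
    3: TaskTarget(3, "stand-up, armrests", "rise", True, 5.0,
                  15.4, 1.7, 67.0, 18.3, 45.7, 0.7, 187.3, 18.8),
    4: TaskTarget(4, "sit-down, armrests", "sit", True, 5.0,
                  16.3, 1.9, 70.4, 15.3, 48.4, 3.5, 186.9, 13.8),
    5: TaskTarget(5, "stand-up, no armrests", "rise", False, 5.0,
                  13.4, 3.3, 73.2, 11.5, 45.1, 5.7, 208.7, 29.2),
    6: TaskTarget(6, "sit-down, no armrests", "sit", False, 5.0,
                  12.8, 1.5, 70.6, 10.9, 47.5, 0.8, 204.8, 9.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Population-level knobs for drawing subject profiles."""

    gain_sd: float = 0.2  # log-normal sigma of per-sensor gains
    placement_sd: float = 3.0  # mm, Gaussian sensor placement error
    noise_sd: float = 0.3  # N, additive measurement noise
    response_exponent: float = 1.0  # compressive nonlinearity (1 = linear)
    quantization_bits: int | None = 10
    quantization_full_scale: float = 100.0  # N
    body_weight_mean: float = 650.0  # N
    body_weight_sd: float = 60.0
    kernel_sigma: float = _KERNEL_SIGMA
    tasks: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_trials: int = 3


@dataclass(frozen=True)
class SubjectProfile:
    """Individual-specific sensor imperfections and anthropometry."""

    seed: int
    gains: np.ndarray  # (12,) positive multipliers, median 1
    placement_offsets: np.ndarray  # (12, 2) mm
    response_exponent: np.ndarray  # (12,) gamma, 1 = linear
    noise_sd: float  # N
    quantization_bits: int | None
    quantization_full_scale: float
    body_weight: float  # N

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gains) <= 0):
            raise ValueError("gains must be positive")
        if np.any(np.asarray(self.response_exponent) <= 0):
            raise ValueError("response exponents must be positive")

    @classmethod
    def draw(cls, seed, config: CohortConfig | None = None) -> "SubjectProfile":
        """Draw a profile; the same seed always yields the same profile."""
        config = config or CohortConfig()
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        gains = np.exp(rng.normal(0.0, config.gain_sd, 12))
        offsets = rng.normal(0.0, config.placement_sd, (12, 2))
        gamma = np.full(12, float(config.response_exponent))
        bw = float(
            np.clip(
                rng.normal(config.body_weight_mean, config.body_weight_sd),
                400.0,
                1000.0,
            )
        )
        return cls(
            seed=int(ss.entropy if np.ndim(ss.entropy) == 0 else ss.entropy[0]),
            gains=gains,
            placement_offsets=offsets,
            response_exponent=gamma,
            noise_sd=config.noise_sd,
            quantization_bits=config.quantization_bits,
            quantization_full_scale=config.quantization_full_scale,
            body_weight=bw,
        )

    @classmethod
    def identity(cls, body_weight: float = 650.0) -> "SubjectProfile":
        """Ideal subject: unit gains, no offsets/noise/quantisation, linear."""
        return cls(
            seed=0,
            gains=np.ones(12),
            placement_offsets=np.zeros((12, 2)),
            response_exponent=np.ones(12),
            noise_sd=0.0,
            quantization_bits=None,
            quantization_full_scale=100.0,
            body_weight=body_weight,
        )


@dataclass
class PressureScene:
    """Blob centres, per-frame amplitudes, and the implied ground truth."""

    centers: np.ndarray  # (K, 2) mm
    amplitudes: np.ndarray  # (m, K) N, >= 0
    fs: float = FS_DEFAULT
    kernel_sigma: float = _KERNEL_SIGMA

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be (K, 2)")
        if self.amplitudes.shape[1] != self.centers.shape[0]:
            raise ValueError("amplitudes must be (m, K) matching centers")
        if np.any(self.amplitudes < 0):
            raise ValueError("blob amplitudes must be >= 0")

    @property
    def total_load(self) -> np.ndarray:
        return self.amplitudes.sum(axis=1)

    def cop(self) -> np.ndarray:
        """(m, 2) amplitude-weighted centroid of the blob centres."""
        load = self.total_load
        if np.any(load <= 0):
            raise ValueError("zero total load frame; COP undefined")
        return (self.amplitudes @ self.centers) / load[:, None]

    @property
    def duration(self) -> float:
        return self.amplitudes.shape[0] / self.fs


# ---------------------------------------------------------------------------
# amplitude solver


def _inset_hull(centers: np.ndarray, margin: float) -> Polygon:
    hull = ConvexHull(centers)
    return Polygon(centers[hull.vertices]).buffer(-margin)


def clamp_to_hull(cop: np.ndarray, centers: np.ndarray, margin: float = _HULL_MARGIN) -> np.ndarray:
    """Project COP targets onto the margin-inset convex hull of the loci."""
    poly = _inset_hull(centers, margin)
    out = np.array(cop, dtype=float)
    inside = contains_xy(poly, out[:, 0], out[:, 1])
    boundary = poly.exterior
    for i in np.flatnonzero(~inside):
        p = boundary.interpolate(boundary.project(Point(out[i, 0], out[i, 1])))
        out[i] = (p.x, p.y)
    return out


def solve_blob_amplitudes(
    cop: np.ndarray,
    load: np.ndarray,
    centers: np.ndarray,
    base_weights: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 300,
) -> np.ndarray:
    """Per-frame blob amplitudes realising a COP path and load profile.

    Solves, per frame, for the exponential tilt theta such that the
    softmax mixture p_k(theta) = w_k exp(theta . r_k) / Z has centroid
    equal to the target COP (damped Newton on the concave dual; the
    Jacobian is the 2x2 positional covariance under p). Returns
    amplitudes A = load * p. Targets must lie strictly inside the convex
    hull of ``centers``.
    """
    cop = np.atleast_2d(np.asarray(cop, dtype=float))
    load = np.atleast_1d(np.asarray(load, dtype=float))
    centers = np.asarray(centers, dtype=float)
    m, k = cop.shape[0], centers.shape[0]
    if load.shape != (m,):
        raise ValueError("load must have one value per COP frame")
    if np.any(load <= 0):
        raise ValueError("total load must be positive in every frame")
    w = np.full(k, 1.0 / k) if base_weights is None else np.asarray(base_weights, float)
    logw = np.log(w / w.sum())

    theta = np.zeros((m, 2))
    c0 = centers.mean(axis=0)
    r = centers - c0  # centred loci, better-conditioned tilts
    target = cop - c0
    for _ in range(max_iter):
        logits = logw + theta @ r.T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        mu = p @ r
        resid = target - mu
        if np.abs(resid).max() < tol:
            break
        # per-frame 2x2 covariance of locus positions under p
        exx = p @ (r[:, 0] ** 2) - mu[:, 0] ** 2
        eyy = p @ (r[:, 1] ** 2) - mu[:, 1] ** 2
        exy = p @ (r[:, 0] * r[:, 1]) - mu[:, 0] * mu[:, 1]
        # Levenberg damping keeps steps sane near the hull boundary
        lam = 1e-9 * (exx + eyy) + 1e-12
        det = (exx + lam) * (eyy + lam) - exy**2
        dx = ((eyy + lam) * resid[:, 0] - exy * resid[:, 1]) / det
        dy = ((exx + lam) * resid[:, 1] - exy * resid[:, 0]) / det
        step = np.column_stack([dx, dy])
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.where(norm > 0.5, 0.5 / np.maximum(norm, 1e-300), 1.0)
        theta += step
    else:
        worst = float(np.abs(target - (p @ r)).max())
        if worst > 1e-6:
            raise RuntimeError(
                f"amplitude solver did not converge (max residual {worst:.3g} mm); "
                "is the target COP inside the convex hull of the loci?"
            )
    return load[:, None] * p


# ---------------------------------------------------------------------------
# sensor forward model


def sample_sensors(
    scene: PressureScene,
    layout: SensorLayout,
    profile: SubjectProfile,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Measure a pressure scene through an imperfect 12-sensor array.

    Each blob's load is apportioned over the (placement-perturbed) sensor
    positions by Gaussian proximity weights normalised per blob; the
    profile then applies gain, response exponent, additive noise, the
    non-negativity floor and optional quantisation. Deterministic for a
    fixed (scene, profile, seed).
    """
    positions = layout.coords + profile.placement_offsets
    d2 = ((positions[:, None, :] - scene.centers[None, :, :]) ** 2).sum(axis=2)
    v = np.exp(-d2 / (2.0 * scene.kernel_sigma**2))
    m_apportion = v / v.sum(axis=0, keepdims=True)  # columns sum to 1
    ideal = scene.amplitudes @ m_apportion.T  # (m, 12), N
    measured = profile.gains * ideal**profile.response_exponent
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        measured = measured + rng.normal(0.0, profile.noise_sd, measured.shape)
    measured = np.maximum(measured, 0.0)
    if profile.quantization_bits is not None:
        step = profile.quantization_full_scale / (2**profile.quantization_bits - 1)
        measured = np.round(measured / step) * step
    return measured


# ---------------------------------------------------------------------------
# task trajectories


def _lowpass_noise(m: int, fs: float, rng, cutoff: float = 1.0) -> np.ndarray:
    b, a = butter(2, cutoff / (fs / 2.0))
    return filtfilt(b, a, rng.standard_normal(m))


def _rescale(series: np.ndarray, target_range: float, target_mean: float) -> np.ndarray:
    s = series - series.mean()
    span = s.max() - s.min()
    if target_range <= 0 or span == 0:
        return np.full_like(s, target_mean)
    return s * (target_range / span) + target_mean


def _jittered(rng, mean: float, sd: float, frac: float) -> float:
    """Normal draw truncated to mean * (1 +/- frac)."""
    lo, hi = mean * (1 - frac), mean * (1 + frac)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _transition_shapes(kind: str, armrest: bool, m: int, fs: float):
    """Normalised AP-excursion and load-fraction profiles for a stand-up;
    sit-downs are the time reverse."""
    t = np.arange(m) / fs
    ap_knots = [(0.0, 0.0), (1.2, 0.05), (2.0, 1.0), (2.9, 0.55), (3.4, 0.5), (5.0, 0.5)]
    if armrest:
        load_knots = [(0.0, 0.35), (1.2, 0.35), (2.0, 0.60), (2.8, 0.95), (3.3, 1.0), (5.0, 1.0)]
    else:
        load_knots = [(0.0, 0.35), (1.2, 0.35), (1.9, 1.10), (2.7, 1.0), (5.0, 1.0)]
    ap = PchipInterpolator(*zip(*[(k, v) for k, v in ap_knots]))(np.clip(t, 0, 5))
    load = PchipInterpolator(*zip(*[(k, v) for k, v in load_knots]))(np.clip(t, 0, 5))
    if kind == "sit":
        ap, load = ap[::-1].copy(), load[::-1].copy()
    return ap, load


def simulate_task(
    task: int,
    profile: SubjectProfile,
    layout: SensorLayout | None = None,
    trial_seed: int | np.random.SeedSequence = 0,
    fs: float = FS_DEFAULT,
    kernel_sigma: float | None = None,
    ml_range: float | None = None,
    ap_range: float | None = None,
    subject: str = "S00",
    foot: str = "left",
    trial: int = 1,
) -> ForceRecording:
    """Simulate one trial of one postural task, with ground-truth COP.

    ``ml_range`` / ``ap_range`` override the per-trial sway-range targets
    (set 0 for a degenerate constant-COP trial). The stored reference
    trajectory is the analytic blob-mixture centroid.
    """
    if task not in TASK_TARGETS:
        raise ValueError(f"unknown task id {task}; valid ids are 1..6")
    spec = TASK_TARGETS[task]
    layout = layout or default_layout()
    ss = (
        trial_seed
        if isinstance(trial_seed, np.random.SeedSequence)
        else np.random.SeedSequence(trial_seed)
    )
    ss_path, ss_sensor = ss.spawn(2)
    rng = np.random.default_rng(ss_path)

    m = int(round(spec.duration * fs))
    centers = np.array(list(ANATOMICAL_LOCI.values()))
    bw_foot = profile.body_weight / 2.0  # one insole carries about half BW

    mlr = _jittered(rng, spec.ml_range, spec.ml_range_sd, 0.3) if ml_range is None else ml_range
    apr = _jittered(rng, spec.ap_range, spec.ap_range_sd, 0.3) if ap_range is None else ap_range
    mlm = float(np.clip(rng.normal(spec.ml_mean, spec.ml_mean_sd), 36.0, 58.0))
    apm = float(np.clip(rng.normal(spec.ap_mean, spec.ap_mean_sd), 160.0, 215.0))

    if spec.kind == "quiet":
        x = _rescale(_lowpass_noise(m, fs, rng), mlr, mlm)
        y = _rescale(_lowpass_noise(m, fs, rng), apr, apm)
        load = np.full(m, bw_foot)
    else:
        ap_shape, load_frac = _transition_shapes(spec.kind, bool(spec.armrest), m, fs)
        y = _rescale(ap_shape + 0.06 * _lowpass_noise(m, fs, rng), apr, apm)
        seatoff = np.exp(-((np.arange(m) / fs - (2.0 if spec.kind == "rise" else 3.0)) ** 2) / 0.5)
        x = _rescale(0.6 * _lowpass_noise(m, fs, rng) + seatoff, mlr, mlm)
        load = bw_foot * load_frac

    cop_target = clamp_to_hull(np.column_stack([x, y]), centers)
    amplitudes = solve_blob_amplitudes(cop_target, load, centers, _BASE_WEIGHTS)
    scene = PressureScene(
        centers=centers,
        amplitudes=amplitudes,
        fs=fs,
        kernel_sigma=kernel_sigma if kernel_sigma is not None else _KERNEL_SIGMA,
    )
    forces = sample_sensors(scene, layout, profile, seed=ss_sensor)
    truth = scene.cop()
    t = np.arange(m) / fs
    return ForceRecording(
        t=t,
        forces=forces,
        ref=CopTrajectory(t=t, x=truth[:, 0], y=truth[:, 1]),
        fs=fs,
        subject=subject,
        foot=foot,
        task=task,
        trial=trial,
        meta={"task_name": spec.name, "body_weight": profile.body_weight},
    )


def make_cohort(
    n_subjects: int,
    config: CohortConfig | None = None,
    master_seed: int = 0,
    layout: SensorLayout | None = None,
    identity_profiles: bool = False,
) -> list[TrialSet]:
    """Simulate a cohort: one TrialSet (6 tasks x 3 trials) per subject-foot.

    All randomness descends from ``master_seed`` through a splittable
    subject -> trial seed tree, so any trial is reproducible in isolation
    and the same master seed always yields an identical cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CohortConfig()
    layout = layout or default_layout()
    root = np.random.SeedSequence(master_seed)
    cohort = []
    for s_idx, s_seed in enumerate(root.spawn(n_subjects)):
        profile_seed, trials_seed = s_seed.spawn(2)
        profile = (
            SubjectProfile.identity()
            if identity_profiles
            else SubjectProfile.draw(profile_seed, config)
        )
        trial_seeds = iter(trials_seed.spawn(len(config.tasks) * config.n_trials))
        recordings = []
        for task in config.tasks:
            for trial in range(1, config.n_trials + 1):
                recordings.append(
                    simulate_task(
                        task,
                        profile,
                        layout,
                        trial_seed=next(trial_seeds),
                        kernel_sigma=config.kernel_sigma,
                        subject=f"S{s_idx:02d}",
                        trial=trial,
                    )
                )
        cohort.append(TrialSet(recordings=recordings))
    return cohort
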