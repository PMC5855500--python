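"""COP estimators: the weighted-mean baseline and the fitted LS model.

The weighted-mean approach estimates the COP as the force-weighted average
of the fixed sensor coordinates,

    x_cop = sum_i x_i F_i / sum_i F_i,

so its accuracy is tied to how well the nominal sensor positions and gains
represent the actual pressure pickup.

The individual-specific model replaces the fixed coordinates with fitted
coefficients. In the default "linear" variant the per-axis prediction is

    x_hat = sum_{i=1..12} c_i F_i + c_tot F_tot,      F_tot = sum_i F_i,

and the coefficients minimise the squared error against a paired reference
trajectory. Because the F_tot column of the design matrix is the exact row
sum of the twelve force columns, the normal equations are singular; the
defined answer is the minimum-norm least-squares solution (SVD
pseudoinverse, relative singular-value cutoff 1e-10). Predictions are
invariant to the one-dimensional coefficient null space (add d to c_tot,
subtract d from every c_i), so the gauge choice is irrelevant downstream.

The "normalized" variant regresses on the force fractions F_i / F_tot
(twelve predictors), which makes the prediction invariant to rescaling all
forces -- the literal ratio form of the weighted-mean family. Coefficient
vectors are stored as length 13 in both variants (the 13th entry is unused
and fixed to 0 for "normalized").

Models are fitted per subject, per foot and per axis, pooling all tasks in
the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SensorLayout
from .recording import CopTrajectory, ForceRecording, as_force_array

__all__ = [
    "CopModel",
    "ZeroLoadError",
    "weighted_mean_cop",
    "build_design_matrix",
    "initial_coefficients",
    "fit_cop_model",
    "predict_cop",
]

N_SENSORS = 12
N_COEFFS = 13
VARIANTS = ("linear", "normalized")


class ZeroLoadError(ValueError):
    """COP is undefined for frames with zero total force."""


@dataclass
class CopModel:
    """Fitted per-axis coefficient vectors plus fit provenance."""

    cx: np.ndarray
    cy: np.ndarray
    variant: str = "linear"
    training_sse: tuple[float, float] = (0.0, 0.0)  # (ML, AP), mm^2
    layout_ref: str | None = None
    initial_cx: np.ndarray | None = None
    initial_cy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cx = np.asarray(self.cx, dtype=float)
        self.cy = np.asarray(self.cy, dtype=float)
        if self.cx.shape != (N_COEFFS,) or self.cy.shape != (N_COEFFS,):
            raise ValueError(f"coefficient vectors must have length {N_COEFFS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        if any(s < 0 for s in self.training_sse):
            raise ValueError("training SSE cannot be negative")


def _times(frames, m: int) -> np.ndarray:
    if isinstance(frames, ForceRecording):
        return frames.t
    return np.arange(m, dtype=float) / 50.0


def weighted_mean_cop(frames, layout: SensorLayout) -> CopTrajectory:
    """Force-weighted average of the sensor coordinates, per frame.

    Raises :class:`ZeroLoadError` (naming the first offending frame) if any
    frame carries no load, since the COP is undefined there.
    """
    forces = as_force_array(frames)
    f_tot = forces.sum(axis=1)
    if np.any(f_tot <= 0):
        idx = int(np.argmax(f_tot <= 0))
        raise ZeroLoadError(f"frame {idx} has zero total force; COP undefined")
    coords = layout.coords
    x = forces @ coords[:, 0] / f_tot
    y = forces @ coords[:, 1] / f_tot
    return CopTrajectory(t=_times(frames, len(x)), x=x, y=y)


def build_design_matrix(frames) -> np.ndarray:
    """(m, 13) predictor matrix: 12 channel forces plus their exact row sum."""
    forces = as_force_array(frames)
    if forces.shape[0] < 1:
        raise ValueError("empty force series")
    return np.column_stack([forces, forces.sum(axis=1)])


def initial_coefficients(layout: SensorLayout) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-seeded starting coefficients.

    The sensor locations seed the per-sensor coefficients (the fitted model
    reduces to a scaled weighted mean at this point); the total-force entry
    starts at 0. The closed-form solution does not depend on these values --
    they are recorded in the model purely as provenance.
    """
    cx0 = np.append(layout.x, 0.0)
    cy0 = np.append(layout.y, 0.0)
    return cx0, cy0


def _predictors(forces: np.ndarray, variant: str) -> np.ndarray:
    if variant == "linear":
        return np.column_stack([forces, forces.sum(axis=1)])
    if variant == "normalized":
        f_tot = forces.sum(axis=1)
        if np.any(f_tot <= 0):
            idx = int(np.argmax(f_tot <= 0))
            raise ZeroLoadError(
                f"frame {idx} has zero total force; normalized predictors undefined"
            )
        return forces / f_tot[:, None]
    raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")


def fit_cop_model(
    frames,
    reference: CopTrajectory,
    variant: str = "linear",
    layout: SensorLayout | None = None,
    rcond: float = 1e-10,
) -> CopModel:
    """Least-squares fit of the per-axis coefficient vectors.

    Solves min_c ||P c - x_ref||^2 per axis, with P the variant's predictor
    matrix, via the SVD minimum-norm solution (relative cutoff ``rcond``).
    The stationarity condition P^T (P c - x_ref) = 0 of the normal
    equations holds at the solution up to floating-point round-off.
    """
    forces = as_force_array(frames)
    m = forces.shape[0]
    if m < 2:
        raise ValueError(f"need at least 2 frames to fit, got {m}")
    if len(reference) != m:
        raise ValueError(
            f"reference length {len(reference)} does not match {m} force frames"
        )
    if not np.all(np.isfinite(forces)):
        raise ValueError("non-finite force values")
    if not np.any(forces):
        raise ValueError("all-zero force matrix: no signal to fit")

    pred = _predictors(forces, variant)
    coeffs = []
    sses = []
    for target in (reference.x, reference.y):
        c, _, _, _ = np.linalg.lstsq(pred, target, rcond=rcond)
        resid = pred @ c - target
        coeffs.append(c)
        sses.append(float(resid @ resid))
    if variant == "normalized":
        coeffs = [np.append(c, 0.0) for c in coeffs]

    init_cx = init_cy = None
    layout_ref = None
    if layout is not None:
        init_cx, init_cy = initial_coefficients(layout)
        layout_ref = f"{layout.name}/{layout.insole_size}"
    return CopModel(
        cx=coeffs[0],
        cy=coeffs[1],
        variant=variant,
        training_sse=(sses[0], sses[1]),
        layout_ref=layout_ref,
        initial_cx=init_cx,
        initial_cy=init_cy,
        meta={"m": m, "rcond": rcond},
    )


def predict_cop(model: CopModel, frames) -> CopTrajectory:
    """Evaluate the fitted linear form on a force series."""
    forces = as_force_array(frames)
    if forces.shape[0] < 1:
        raise ValueError("empty force series")
    pred = _predictors(forces, model.variant)
    if model.variant == "normalized":
        x = pred @ model.cx[:N_SENSORS]
        y = pred @ model.cy[:N_SENSORS]
    else:
        x = pred @ model.cx
        y = pred @ model.cy
    return CopTrajectory(t=_times(frames, len(x)), x=x, y=y)


def training_gradient(model: CopModel, frames, reference: CopTrajectory) -> float:
    """Max-abs entry of the per-axis normal-equation gradient P^T (P c - x).

    Diagnostic for the stationarity contract of the least-squares fit; a
    converged fit returns a value that is tiny relative to
    ||P^T||_inf * ||x||_inf.
    """
    forces = as_force_array(frames)
    pred = _predictors(forces, model.variant)
    worst = 0.0
    for c, target in ((model.cx, reference.x), (model.cy, reference.y)):
        cc = c[:N_SENSORS] if model.variant == "normalized" else c
        g = pred.T @ (pred @ cc - target)
        worst = max(worst, float(np.abs(g).max()))
    return worst
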