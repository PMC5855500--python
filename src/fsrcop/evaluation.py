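"""Three-fold cross-validated evaluation of COP estimators.

Protocol: each subject-foot contributes six tasks x three trials. Fold k
holds trial k of every task, so every fold is task-complete. For each of
the three train/test rotations the model is fitted on the concatenated
frames of two folds and evaluated on the third; the weighted-mean baseline
needs no fitting and is evaluated on the same test folds. Metrics are
computed per fold and axis on the concatenated test trajectory: RMSE,
Pearson correlation with its two-sided p-value, and the maximum/minimum
per-sample absolute error (MaxE/MinE). Fold metrics are aggregated as
mean +/- SD across the three folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import SensorLayout
from .model import fit_cop_model, predict_cop, weighted_mean_cop
from .recording import CopTrajectory, TrialSet

__all__ = [
    "FoldStructureError",
    "EvaluationReport",
    "ComparisonReport",
    "rmse",
    "correlation",
    "max_min_error",
    "estimate_lag",
    "make_folds",
    "three_fold_cv",
    "compare_methods",
    "evaluate_cohort",
]

AXES = ("ml", "ap")
ESTIMATOR_MODEL = "model"
ESTIMATOR_BASELINE = "weighted-mean"
N_FOLDS = 3


class FoldStructureError(ValueError):
    """Raised when a trial set cannot form three task-complete folds."""


def rmse(est, ref) -> float:
    """Root-mean-square difference of two equal-length series (mm)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError(f"length mismatch or empty: {est.shape} vs {ref.shape}")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def correlation(est, ref) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value (t-distribution, n-2 df)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 3:
        raise ValueError("correlation needs at least 3 samples")
    if np.std(est) == 0 or np.std(ref) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    res = stats.pearsonr(est, ref)
    return float(res.statistic), float(res.pvalue)


def max_min_error(est, ref) -> tuple[float, float]:
    """Largest and smallest per-sample absolute error (mm)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError(f"length mismatch or empty: {est.shape} vs {ref.shape}")
    err = np.abs(est - ref)
    return float(err.max()), float(err.min())


def estimate_lag(est, ref, max_lag: int = 25) -> int:
    """Integer-sample lag of ``est`` relative to ``ref`` by cross-correlation.

    Positive lag means ``est`` trails ``ref``. Utility for recordings whose
    acquisition chains were synchronised manually; the CV harness assumes
    pre-aligned series and never applies this automatically.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise ValueError("need two equal-length series of at least 3 samples")
    e = est - est.mean()
    r = ref - ref.mean()
    lags = range(-max_lag, max_lag + 1)
    scores = []
    for lag in lags:
        if lag >= 0:
            a, b = e[lag:], r[: e.size - lag]
        else:
            a, b = e[:lag], r[-lag:]
        scores.append(float(a @ b) / max(a.size, 1))
    return list(lags)[int(np.argmax(scores))]


def make_folds(trials: TrialSet, mode: str = "by_trial", seed=None) -> dict[int, list]:
    """Partition a trial set into three task-complete folds.

    ``by_trial`` (default) assigns trial k of every task to fold k -- the
    direct reading of the protocol. ``random`` permutes, per task, which
    trial lands in which fold (seeded), for robustness checks.
    """
    tasks = trials.tasks
    by_key = {(r.task, r.trial): r for r in trials.recordings}
    missing = [
        (task, trial)
        for task in tasks
        for trial in range(1, N_FOLDS + 1)
        if (task, trial) not in by_key
    ]
    extra = sorted(k for k in by_key if k[1] not in range(1, N_FOLDS + 1))
    if missing or extra:
        raise FoldStructureError(
            f"need exactly trials 1..{N_FOLDS} per task; "
            f"missing {missing}, unexpected {extra}"
        )
    if mode == "by_trial":
        assignment = {task: list(range(1, N_FOLDS + 1)) for task in tasks}
    elif mode == "random":
        rng = np.random.default_rng(seed)
        assignment = {
            task: list(rng.permutation(range(1, N_FOLDS + 1))) for task in tasks
        }
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    folds: dict[int, list] = {k: [] for k in range(1, N_FOLDS + 1)}
    for task in tasks:
        for fold, trial in enumerate(assignment[task], start=1):
            folds[fold].append(by_key[(task, trial)])
    return folds


@dataclass
class EvaluationReport:
    """Per-fold, per-axis, per-estimator metrics for one subject-foot."""

    subject: str
    foot: str
    variant: str
    rows: list[dict]
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def subset(self, estimator: str) -> "EvaluationReport":
        rows = [r for r in self.rows if r["estimator"] == estimator]
        if not rows:
            raise ValueError(f"no rows for estimator {estimator!r}")
        return EvaluationReport(
            subject=self.subject,
            foot=self.foot,
            variant=self.variant,
            rows=rows,
            meta=dict(self.meta),
        )

    @property
    def estimators(self) -> list[str]:
        return sorted({r["estimator"] for r in self.rows})

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD of every metric across folds, per estimator x axis."""
        df = self.to_dataframe()
        agg = df.groupby(["estimator", "axis"])[
            ["rmse", "cc", "max_e", "min_e"]
        ].agg(["mean", "std"])
        agg.columns = ["_".join(c) for c in agg.columns]
        return agg

    def mean_metric(self, estimator: str, axis: str, metric: str = "rmse") -> float:
        vals = [
            r[metric]
            for r in self.rows
            if r["estimator"] == estimator and r["axis"] == axis
        ]
        if not vals:
            raise ValueError(f"no rows for ({estimator}, {axis})")
        return float(np.mean(vals))


def _concat_test(recordings, drop_zero_load: bool):
    forces = np.vstack([r.forces for r in recordings])
    ref_x = np.concatenate([r.ref.x for r in recordings])
    ref_y = np.concatenate([r.ref.y for r in recordings])
    n_dropped = 0
    if drop_zero_load:
        keep = forces.sum(axis=1) > 0
        n_dropped = int(np.sum(~keep))
        forces, ref_x, ref_y = forces[keep], ref_x[keep], ref_y[keep]
    t = np.arange(forces.shape[0], dtype=float)
    return forces, CopTrajectory(t=t, x=ref_x, y=ref_y), n_dropped


def three_fold_cv(
    trials: TrialSet,
    layout: SensorLayout,
    variant: str = "normalized",
    estimators=(ESTIMATOR_MODEL, ESTIMATOR_BASELINE),
    fold_mode: str = "by_trial",
    seed=None,
    drop_zero_load: bool = False,
) -> EvaluationReport:
    """Run the three-fold protocol for the fitted model and/or the baseline."""
    for r in trials.recordings:
        if r.ref is None:
            raise ValueError(
                f"recording task {r.task} trial {r.trial} has no reference COP"
            )
    folds = make_folds(trials, mode=fold_mode, seed=seed)
    rows: list[dict] = []
    for test_fold in sorted(folds):
        train_recs = [
            r for k in sorted(folds) if k != test_fold for r in folds[k]
        ]
        test_recs = folds[test_fold]
        forces_te, ref_te, n_dropped = _concat_test(test_recs, drop_zero_load)
        estimates: dict[str, CopTrajectory] = {}
        if ESTIMATOR_MODEL in estimators:
            forces_tr, ref_tr, _ = _concat_test(train_recs, drop_zero_load)
            mdl = fit_cop_model(forces_tr, ref_tr, variant=variant, layout=layout)
            estimates[ESTIMATOR_MODEL] = predict_cop(mdl, forces_te)
        if ESTIMATOR_BASELINE in estimators:
            estimates[ESTIMATOR_BASELINE] = weighted_mean_cop(forces_te, layout)
        for estimator, est in estimates.items():
            for axis in AXES:
                e, r_ = est.axis(axis), ref_te.axis(axis)
                cc, cc_p = correlation(e, r_)
                max_e, min_e = max_min_error(e, r_)
                rows.append(
                    {
                        "fold": test_fold,
                        "axis": axis,
                        "estimator": estimator,
                        "rmse": rmse(e, r_),
                        "cc": cc,
                        "cc_p_value": cc_p,
                        "max_e": max_e,
                        "min_e": min_e,
                        "n_samples": int(e.size),
                        "n_dropped_zero_load": n_dropped,
                    }
                )
    return EvaluationReport(
        subject=trials.subject,
        foot=trials.foot,
        variant=variant,
        rows=rows,
        meta={"fold_mode": fold_mode, "seed": seed, "estimators": list(estimators)},
    )


@dataclass
class ComparisonReport:
    """Paired per-fold differences between two estimators (B minus A)."""

    rows: list[dict]
    estimator_a: str
    estimator_b: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        """Per-axis mean differences and the fraction of folds A wins."""
        df = self.to_dataframe()
        out = []
        for axis, g in df.groupby("axis"):
            wins = float(np.mean(g["d_rmse"] > 0))
            ties = float(np.mean(g["d_rmse"] == 0))
            out.append(
                {
                    "axis": axis,
                    "mean_d_rmse": float(g["d_rmse"].mean()),
                    "mean_d_cc": float(g["d_cc"].mean()),
                    "win_fraction": wins,
                    "tie_fraction": ties,
                }
            )
        return pd.DataFrame(out).set_index("axis")


def compare_methods(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    estimator_a: str | None = None,
    estimator_b: str | None = None,
) -> ComparisonReport:
    """Pair fold x axis metrics of two reports; d_rmse > 0 means A wins."""
    if estimator_a is None:
        (estimator_a,) = report_a.estimators
    if estimator_b is None:
        (estimator_b,) = report_b.estimators
    a = {
        (r["fold"], r["axis"]): r
        for r in report_a.rows
        if r["estimator"] == estimator_a
    }
    b = {
        (r["fold"], r["axis"]): r
        for r in report_b.rows
        if r["estimator"] == estimator_b
    }
    if set(a) != set(b):
        raise ValueError(
            f"mismatched fold structure: {sorted(set(a) ^ set(b))} unpaired"
        )
    rows = []
    for key in sorted(a):
        ra, rb = a[key], b[key]
        rows.append(
            {
                "fold": key[0],
                "axis": key[1],
                "rmse_a": ra["rmse"],
                "rmse_b": rb["rmse"],
                "d_rmse": rb["rmse"] - ra["rmse"],
                "cc_a": ra["cc"],
                "cc_b": rb["cc"],
                "d_cc": ra["cc"] - rb["cc"],
            }
        )
    return ComparisonReport(rows=rows, estimator_a=estimator_a, estimator_b=estimator_b)


def evaluate_cohort(
    cohort: list[TrialSet],
    layout: SensorLayout,
    variant: str = "normalized",
) -> pd.DataFrame:
    """CV both estimators over a cohort; one row per subject-foot x axis.

    ``model_wins`` flags subject-feet where the fitted model's mean-across-
    folds RMSE is strictly below the weighted-mean baseline's.
    """
    rows = []
    for trials in cohort:
        report = three_fold_cv(trials, layout, variant=variant)
        for axis in AXES:
            m_rmse = report.mean_metric(ESTIMATOR_MODEL, axis, "rmse")
            b_rmse = report.mean_metric(ESTIMATOR_BASELINE, axis, "rmse")
            rows.append(
                {
                    "subject": trials.subject,
                    "foot": trials.foot,
                    "axis": axis,
                    "model_rmse": m_rmse,
                    "baseline_rmse": b_rmse,
                    "model_cc": report.mean_metric(ESTIMATOR_MODEL, axis, "cc"),
                    "baseline_cc": report.mean_metric(ESTIMATOR_BASELINE, axis, "cc"),
                    "model_wins": m_rmse < b_rmse,
                }
            )
    return pd.DataFrame(rows)
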