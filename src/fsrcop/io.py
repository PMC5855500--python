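"""Readers and writers for the package's text artifacts.

Recording CSV dialect: comma-separated, '.' decimal, UTF-8; a leading
block of ``# key: value`` comment lines carries units, sampling rate and
subject/task/trial/foot metadata; then a header row ``t,F1..F12[,ref_x,
ref_y]``. Floats are written with 17 significant digits so write -> read
round-trips are lossless.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CopModel
from .evaluation import EvaluationReport
from .recording import CopTrajectory, ForceRecording, TrialSet

__all__ = [
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "read_trial_sets",
    "write_trial_set",
    "read_model",
    "write_model",
    "read_report",
    "write_report",
]

FORCE_COLUMNS = [f"F{i}" for i in range(1, 13)]
REF_COLUMNS = ["ref_x", "ref_y"]
_FLOAT_FMT = "%.17g"


class RecordingFormatError(ValueError):
    """Raised for malformed recording CSVs, with a line number when known."""


def write_recording(rec: ForceRecording, path) -> None:
    meta = {
        "format": "fsrcop-recording-v1",
        "fs_hz": rec.fs,
        "units": "t=s, F=N, ref=mm",
        "subject": rec.subject,
        "foot": rec.foot,
        "task": rec.task,
        "trial": rec.trial,
    }
    cols = {"t": rec.t}
    for i, name in enumerate(FORCE_COLUMNS):
        cols[name] = rec.forces[:, i]
    if rec.ref is not None:
        cols["ref_x"] = rec.ref.x
        cols["ref_y"] = rec.ref.y
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_recording(path) -> ForceRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    n_comment = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise RecordingFormatError(f"{path}: no data rows")
    try:
        df = pd.read_csv(
            _io.StringIO("".join(body_lines)), float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingFormatError(f"{path}: unparseable CSV body: {exc}") from exc

    for col in ["t"] + FORCE_COLUMNS:
        if col not in df.columns:
            raise RecordingFormatError(f"{path}: missing column {col}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            # +2 header row offset, +1 one-based, first offending sample is bad+1
            line_no = n_comment + 2 + int(bad[0]) + 1
            raise RecordingFormatError(
                f"{path}: non-monotone time at line {line_no} "
                f"(t[{bad[0] + 1}] <= t[{bad[0]}])"
            )
    fs = float(meta.get("fs_hz", 50.0))
    if t.size > 1:
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
            raise RecordingFormatError(
                f"{path}: sample spacing inconsistent with header fs_hz={fs}"
            )
    forces = df[FORCE_COLUMNS].to_numpy(dtype=float)
    ref = None
    if all(c in df.columns for c in REF_COLUMNS):
        ref = CopTrajectory(
            t=t,
            x=df["ref_x"].to_numpy(dtype=float),
            y=df["ref_y"].to_numpy(dtype=float),
        )
    return ForceRecording(
        t=t,
        forces=forces,
        ref=ref,
        fs=fs,
        subject=meta.get("subject", "S00"),
        foot=meta.get("foot", "left"),
        task=int(meta.get("task", 1)),
        trial=int(meta.get("trial", 1)),
        meta={k: v for k, v in meta.items() if k not in
              ("format", "fs_hz", "units", "subject", "foot", "task", "trial")},
    )


def recording_filename(rec: ForceRecording) -> str:
    return f"{rec.subject}_{rec.foot}_task{rec.task}_trial{rec.trial}.csv"


def write_trial_set(trials: TrialSet, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in trials.recordings:
        p = outdir / recording_filename(rec)
        write_recording(rec, p)
        paths.append(p)
    return paths


def read_trial_sets(paths_or_dir) -> list[TrialSet]:
    """Read recordings and group them into per-subject-foot trial sets."""
    if isinstance(paths_or_dir, (str, Path)) and Path(paths_or_dir).is_dir():
        paths = sorted(Path(paths_or_dir).glob("*.csv"))
    else:
        paths = [Path(p) for p in paths_or_dir]
    if not paths:
        raise RecordingFormatError("no recording CSVs found")
    groups: dict[tuple[str, str], list[ForceRecording]] = {}
    for p in paths:
        rec = read_recording(p)
        groups.setdefault((rec.subject, rec.foot), []).append(rec)
    return [TrialSet(recordings=recs) for _, recs in sorted(groups.items())]


# ---------------------------------------------------------------------------
# model / report JSON


def write_model(model: CopModel, path) -> None:
    doc = {
        "format": "fsrcop-model-v1",
        "variant": model.variant,
        "cx": list(model.cx),
        "cy": list(model.cy),
        "training_sse": list(model.training_sse),
        "layout_ref": model.layout_ref,
        "initial_cx": None if model.initial_cx is None else list(model.initial_cx),
        "initial_cy": None if model.initial_cy is None else list(model.initial_cy),
        "meta": model.meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_model(path) -> CopModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("variant", "cx", "cy"):
        if key not in doc:
            raise ValueError(f"model JSON missing field '{key}'")
    return CopModel(
        cx=np.array(doc["cx"], dtype=float),
        cy=np.array(doc["cy"], dtype=float),
        variant=doc["variant"],
        training_sse=tuple(doc.get("training_sse", (0.0, 0.0))),
        layout_ref=doc.get("layout_ref"),
        initial_cx=None if doc.get("initial_cx") is None else np.array(doc["initial_cx"]),
        initial_cy=None if doc.get("initial_cy") is None else np.array(doc["initial_cy"]),
        meta=doc.get("meta", {}),
    )


def write_report(report: EvaluationReport, path, csv_path=None) -> None:
    doc = {
        "format": "fsrcop-report-v1",
        "subject": report.subject,
        "foot": report.foot,
        "variant": report.variant,
        "rows": report.rows,
        "meta": report.meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    if csv_path is not None:
        df = report.to_dataframe()
        df.insert(0, "subject", report.subject)
        df.insert(1, "foot", report.foot)
        df.to_csv(csv_path, index=False)


def read_report(path) -> EvaluationReport:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return EvaluationReport(
        subject=doc["subject"],
        foot=doc["foot"],
        variant=doc["variant"],
        rows=doc["rows"],
        meta=doc.get("meta", {}),
    )
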