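"""Reading and writing trajectory CSV files and fit-result JSON.

Trajectory CSV format::

    # glottifit trajectory v1
    # unit=cm
    # fps=4000
    # sex=F                (optional)
    # axis_length_px=160   (optional)
    # truth_Ql=1.2         (optional ground-truth metadata, synthetic data)
    frame,time_ms,left,right
    0,0.000000,0.0301234,0.0287654
    ...

Values round-trip at full double precision; the reader validates the
header, monotone consecutive frames, uniform sampling and non-negative
values, reporting offending line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParseError
from .optimize import FitResult, RunRecord
from .signals import TrajectoryPair

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_result_json",
    "write_result_json",
]

FORMAT_TAG = "glottifit trajectory v1"
RESULT_VERSION = 1


def write_trajectory_csv(pair: TrajectoryPair, path, meta: dict | None = None) -> None:
    """Write a trajectory pair with metadata comment lines."""
    meta = dict(pair.meta) | (meta or {})
    truth = meta.pop("truth", None)
    lines = [f"# {FORMAT_TAG}", f"# unit={pair.unit}", f"# fps={pair.sample_rate:g}"]
    if pair.px_scale is not None:
        lines.append(f"# px_scale={pair.px_scale!r}")
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    if truth:
        for key, value in truth.items():
            lines.append(f"# truth_{key}={value}")
    lines.append("frame,time_ms,left,right")
    dt_ms = 1000.0 / pair.sample_rate
    for i, (l, r) in enumerate(zip(pair.left, pair.right)):
        lines.append(f"{i},{i * dt_ms:.6f},{float(l)!r},{float(r)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_csv(path) -> TrajectoryPair:
    """Read and validate a trajectory CSV; metadata lands in ``pair.meta``."""
    text = Path(path).read_text().splitlines()
    meta: dict = {}
    header_line = None
    rows = []
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if header_line is None:
            if line.replace(" ", "") != "frame,time_ms,left,right":
                raise ParseError(
                    f"expected header 'frame,time_ms,left,right', got {line!r}", lineno
                )
            header_line = lineno
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(f"expected 4 comma-separated fields, got {len(parts)}", lineno)
        try:
            rows.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3]), lineno))
        except ValueError as exc:
            raise ParseError(f"malformed numeric value ({exc})", lineno) from None

    if "fps" not in meta:
        raise ParseError("missing required metadata line '# fps=...'")
    if "unit" not in meta:
        raise ParseError("missing required metadata line '# unit=...'")
    if header_line is None or len(rows) < 2:
        raise ParseError("no trajectory data found")

    fps = float(meta["fps"])
    frames = np.array([r[0] for r in rows])
    times = np.array([r[1] for r in rows])
    left = np.array([r[2] for r in rows])
    right = np.array([r[3] for r in rows])

    steps = np.diff(frames)
    if np.any(steps != 1):
        bad = int(np.flatnonzero(steps != 1)[0])
        raise ParseError("frame numbers must increase by 1", rows[bad + 1][4])
    dt = np.diff(times)
    if not np.allclose(dt, 1000.0 / fps, rtol=1e-6, atol=1e-6):
        bad = int(np.flatnonzero(~np.isclose(dt, 1000.0 / fps, rtol=1e-6, atol=1e-6))[0])
        raise ParseError("non-uniform sampling interval", rows[bad + 1][4])
    neg = (left < 0) | (right < 0)
    if np.any(neg):
        raise ParseError("negative trajectory value", rows[int(np.flatnonzero(neg)[0])][4])

    px_scale = float(meta["px_scale"]) if "px_scale" in meta else None
    truth = {k[len("truth_"):]: v for k, v in meta.items() if k.startswith("truth_")}
    extra = {
        k: v for k, v in meta.items()
        if k not in ("fps", "unit", "px_scale") and not k.startswith("truth_")
    }
    if truth:
        extra["truth"] = truth
    return TrajectoryPair(
        left=left, right=right, sample_rate=fps, unit=meta["unit"],
        px_scale=px_scale, meta=extra,
    )


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def write_result_json(fit: FitResult, path) -> None:
    """Serialize a complete per-subject fit result."""
    from . import __version__

    doc = {
        "format_version": RESULT_VERSION,
        "software_version": __version__,
        "subject_id": fit.subject_id,
        "selected": {
            "Ql": fit.best.params.Ql,
            "Qr": fit.best.params.Qr,
            "Ps_cmH2O": fit.best.params.Ps,
            "gamma": fit.best.gamma,
            "algorithm": fit.best.algorithm,
            "cost": fit.best.cost,
            "Qlr": fit.qlr,
            "f_El": fit.f_el, "f_Er": fit.f_er,
            "f_Ml": fit.f_ml, "f_Mr": fit.f_mr,
            "success": fit.success.to_dict(),
        },
        "runs": [r.to_dict() for r in fit.records],
        "config": fit.config,
    }
    Path(path).write_text(json.dumps(_to_jsonable(doc), indent=1) + "\n")


def read_result_json(path) -> FitResult:
    """Reconstruct a ``FitResult`` from its JSON serialization."""
    from .evaluate import SuccessReport

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from None
    for key in ("subject_id", "selected", "runs"):
        if key not in doc:
            raise ParseError(f"result JSON missing required key {key!r}")
    records = [RunRecord.from_dict(d) for d in doc["runs"]]
    sel = doc["selected"]
    matching = [
        r for r in records
        if r.algorithm == sel["algorithm"] and r.cost == sel["cost"]
    ]
    if not matching:
        raise ParseError("selected run not present among recorded runs")
    best = matching[0]
    s = sel["success"]
    success = SuccessReport(
        frequency_ok=s["frequency"],
        closure_ok=s["closure"],
        amplitude_ok=s["amplitude"],
        freq_deviation_l=s["freq_deviation_pct"][0],
        freq_deviation_r=s["freq_deviation_pct"][1],
        exp_amplitude_range_l=tuple(s["exp_amplitude_range"][0]),
        exp_amplitude_range_r=tuple(s["exp_amplitude_range"][1]),
        model_amplitude_l=s["model_amplitude"][0],
        model_amplitude_r=s["model_amplitude"][1],
    )
    return FitResult(
        subject_id=doc["subject_id"],
        records=records,
        best=best,
        qlr=sel["Qlr"],
        f_el=sel["f_El"], f_er=sel["f_Er"],
        f_ml=sel["f_Ml"], f_mr=sel["f_Mr"],
        success=success,
        config=doc.get("config", {}),
    )
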