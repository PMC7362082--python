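"""CSV readers/writers, run records, and curve comparison utilities.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, LF line endings,
header always present, numbers rendered with 9 significant digits.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ForceExtensionCurve

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "read_reference_csv",
    "rms_deviation",
    "RunRecord",
    "write_run_record",
]


def write_curve_csv(curve: ForceExtensionCurve, path: str | Path) -> Path:
    """Write a curve as CSV: independent variable, force, extra columns."""
    path = Path(path)
    columns: dict[str, np.ndarray] = {
        curve.x_label: np.asarray(curve.x),
        curve.force_label: np.asarray(curve.force),
    }
    for name, values in curve.extra.items():
        columns[name] = np.asarray(values)

    lines = [",".join(columns)]
    n = curve.n_samples
    for i in range(n):
        cells = []
        for values in columns.values():
            v = values[i]
            if isinstance(v, (bool, np.bool_)):
                cells.append("1" if v else "0")
            else:
                cells.append(f"{float(v):.9g}")
        lines.append(",".join(cells))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise OSError(f"cannot write curve CSV to {path}: {exc}") from exc
    return path


def read_curve_csv(path: str | Path, scale: str = "fiber") -> ForceExtensionCurve:
    """Read back a CSV written by :func:`write_curve_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns")
    x_label, force_label = df.columns[0], df.columns[1]
    extra = {c: df[c].to_numpy(dtype=float) for c in df.columns[2:]}
    return ForceExtensionCurve(
        scale=scale,
        x=df[x_label].to_numpy(dtype=float),
        force=df[force_label].to_numpy(dtype=float),
        x_label=x_label,
        force_label=force_label,
        extra=extra,
        metadata={"source": str(path)},
    )


def read_reference_csv(path: str | Path, scale: str = "fiber") -> ForceExtensionCurve:
    """Read a user-supplied two-column (x, force) reference curve.

    An optional header row is accepted.  Rows breaking the strictly
    increasing order of the independent variable are dropped with a
    warning; non-numeric data rows raise an error naming their lines.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    rows: list[tuple[float, float]] = []
    bad_lines: list[int] = []
    n_data = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = [c.strip() for c in line.split(",")]
        if len(parts) < 2:
            bad_lines.append(lineno)
            continue
        try:
            x, f = float(parts[0]), float(parts[1])
        except ValueError:
            if n_data == 0 and not bad_lines and lineno == 1:
                continue  # header row
            bad_lines.append(lineno)
            continue
        rows.append((x, f))
        n_data += 1
    if bad_lines:
        raise ValueError(f"{path}: non-numeric rows at lines {bad_lines}")
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")

    kept_x: list[float] = []
    kept_f: list[float] = []
    dropped = 0
    for x, f in rows:
        if kept_x and x <= kept_x[-1]:
            dropped += 1
            continue
        kept_x.append(x)
        kept_f.append(f)
    if dropped:
        warnings.warn(
            f"{path}: dropped {dropped} row(s) violating strictly increasing order",
            stacklevel=2,
        )
    return ForceExtensionCurve(
        scale=scale,
        x=np.array(kept_x),
        force=np.array(kept_f),
        metadata={"source": str(path), "dropped_rows": dropped},
    )


def rms_deviation(model: ForceExtensionCurve, ref: ForceExtensionCurve) -> float:
    """RMS force difference at the reference abscissae within the overlap.

    The model curve is linearly interpolated onto the reference grid, so
    the measure is not symmetric in its arguments.
    """
    mx = np.asarray(model.x, dtype=float)
    my = np.asarray(model.force, dtype=float)
    rx = np.asarray(ref.x, dtype=float)
    ry = np.asarray(ref.force, dtype=float)
    lo = max(mx.min(), rx.min())
    hi = min(mx.max(), rx.max())
    if hi < lo:
        raise ValueError("curves have no overlapping range")
    mask = (rx >= lo) & (rx <= hi)
    if not np.any(mask):
        raise ValueError("no reference samples inside the overlapping range")
    interp = np.interp(rx[mask], mx, my)
    return float(np.sqrt(np.mean((interp - ry[mask]) ** 2)))


@dataclass
class RunRecord:
    """Machine-readable record of one CLI run, sufficient to reproduce it."""

    command: str
    flags: dict
    parameters: dict
    geometry: dict
    clot: dict
    simulation: dict
    derived_counts: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def write_run_record(record: RunRecord, out_path: str | Path) -> Path:
    """Write the record next to an output file as ``<out>.run.json``."""
    out_path = Path(out_path)
    record_path = out_path.with_name(out_path.name + ".run.json")
    record_path.write_text(record.to_json() + "\n", encoding="utf-8")
    return record_path
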