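"""Delimited-text I/O for orientation and paired fields.

Angle-field files are CSV or TSV (auto-detected from the header line) with
a required header row.  Accepted layouts:

* single construct: columns ``x, y, angle`` or just ``angle``;
* paired constructs: columns ``angle_p, angle_q`` with optional ``x, y``
  and ``weight``.

Angles are radians by default; pass ``degrees=True`` to convert on read
(and write).  Masked pixels are simply absent from the file.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import OrientationField, PairedField

__all__ = [
    "read_angle_field",
    "read_paired_field",
    "write_angle_field",
    "write_paired_field",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_angle_field(path, degrees: bool = False, label: str = "") -> OrientationField:
    """Read a single-construct angle field from a CSV/TSV file."""
    df = _read_table(path)
    _require(df, ["angle"], path)
    angles = df["angle"].to_numpy(dtype=float)
    if degrees:
        angles = np.deg2rad(angles)
    coords = None
    if "x" in df.columns and "y" in df.columns:
        coords = df[["x", "y"]].to_numpy(dtype=float)
    return OrientationField(angles, coords=coords, label=label or Path(path).stem)


def read_paired_field(path, degrees: bool = False) -> PairedField:
    """Read an index-paired two-construct field from a CSV/TSV file."""
    df = _read_table(path)
    _require(df, ["angle_p", "angle_q"], path)
    p = df["angle_p"].to_numpy(dtype=float)
    q = df["angle_q"].to_numpy(dtype=float)
    if degrees:
        p, q = np.deg2rad(p), np.deg2rad(q)
    weights = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
    coords = None
    if "x" in df.columns and "y" in df.columns:
        coords = df[["x", "y"]].to_numpy(dtype=float)
    return PairedField(p, q, weights=weights, coords=coords)


def write_angle_field(field: OrientationField, path, degrees: bool = False) -> None:
    """Write a single-construct field as CSV (columns x, y, angle or angle)."""
    angles = np.rad2deg(field.angles) if degrees else field.angles
    if field.coords is not None:
        df = pd.DataFrame({"x": field.coords[:, 0], "y": field.coords[:, 1], "angle": angles})
    else:
        df = pd.DataFrame({"angle": angles})
    df.to_csv(path, index=False)


def write_paired_field(pf: PairedField, path, degrees: bool = False) -> None:
    """Write a paired field as CSV (angle_p, angle_q plus optional x, y, weight)."""
    conv = math.degrees(1.0) if degrees else 1.0
    data = {}
    if pf.coords is not None:
        data["x"] = pf.coords[:, 0]
        data["y"] = pf.coords[:, 1]
    data["angle_p"] = pf.p_angles * conv
    data["angle_q"] = pf.q_angles * conv
    if pf.weights is not None:
        data["weight"] = pf.weights
    pd.DataFrame(data).to_csv(path, index=False)
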