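"""OpenSim-style .sto/.mot storage files and gait-trial serialisation.

The dialect: free ``key=value`` header lines including ``nRows=``,
``nColumns=`` and optionally ``inDegrees=yes|no``, terminated by
``endheader``; a tab/whitespace-delimited column-label line whose first
column is ``time``; then the data body.  When ``inDegrees=yes`` all
non-time columns are converted to radians on read (so files holding mixed
angle/moment tables should be written in radians, ``inDegrees=no`` — the
convention this package's writers follow for trial files).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gait_synth import JOINTS, SIDES, GaitTrial

__all__ = ["StoFormatError", "read_sto", "write_sto", "trial_to_table", "write_trial", "read_trial"]


class StoFormatError(ValueError):
    """Malformed .sto/.mot content; the message names the offending line."""


def read_sto(path) -> tuple[pd.DataFrame, dict]:
    """Parse a .sto/.mot file.

    Returns ``(table, header)``: the table has a ``time`` first column
    (seconds, strictly increasing) and float data columns (radians if the
    file declared degrees); ``header`` holds the raw header key/values.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
        elif line.strip():
            header.setdefault("name", line.strip())
    if body_start is None:
        raise StoFormatError(f"{path}: no 'endheader' line found")
    rows = [ln for ln in lines[body_start:] if ln.strip()]
    if not rows:
        raise StoFormatError(f"{path}: missing column-label line after endheader (line {body_start + 1})")
    columns = rows[0].split()
    data = []
    for offset, ln in enumerate(rows[1:], start=2):
        parts = ln.split()
        if len(parts) != len(columns):
            raise StoFormatError(
                f"{path}: row {offset} has {len(parts)} fields, expected {len(columns)}"
            )
        data.append([float(v) for v in parts])
    table = pd.DataFrame(data, columns=columns)
    n_rows = header.get("nRows")
    if n_rows is not None and int(n_rows) != len(table):
        raise StoFormatError(f"{path}: nRows={n_rows} but body has {len(table)} rows")
    n_cols = header.get("nColumns")
    if n_cols is not None and int(n_cols) != len(columns):
        raise StoFormatError(f"{path}: nColumns={n_cols} but body has {len(columns)} columns")
    if columns[0] != "time":
        raise StoFormatError(f"{path}: first column must be 'time', got {columns[0]!r}")
    if np.any(np.diff(table["time"].to_numpy()) <= 0):
        raise StoFormatError(f"{path}: time column is not strictly increasing")
    if header.get("inDegrees", "no").lower() == "yes":
        for col in columns[1:]:
            table[col] = np.deg2rad(table[col])
    return table, header


def write_sto(table: pd.DataFrame, path, in_degrees: bool = False, name: str = "data", extra_header: dict | None = None) -> None:
    """Write a table as .sto; the inverse of :func:`read_sto`.

    With ``in_degrees`` the non-time columns are converted from radians to
    degrees on disk and the header declares ``inDegrees=yes``.
    """
    if table.shape[0] == 0 or table.shape[1] < 2:
        raise ValueError("table must have at least one row and a data column besides time")
    if table.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    out = table.copy()
    if in_degrees:
        for col in out.columns[1:]:
            out[col] = np.rad2deg(out[col])
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"{key}={value}\n")
        fh.write(f"nRows={len(out)}\nnColumns={out.shape[1]}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("\t".join(out.columns) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def trial_to_table(trial: GaitTrial) -> pd.DataFrame:
    """Flatten a trial into one table: angles, velocities, moments per channel."""
    cols = {"time": trial.time}
    for joint in JOINTS:
        for side in SIDES:
            tag = f"{joint}_{side[0]}"
            cols[f"{tag}_angle"] = trial.angles[(joint, side)]
            cols[f"{tag}_speed"] = trial.velocities[(joint, side)]
            cols[f"{tag}_moment"] = trial.moments[(joint, side)]
    return pd.DataFrame(cols)


def write_trial(trial: GaitTrial, path) -> None:
    """Serialise a trial as a single .sto (radians/N*m; anthropometry in header)."""
    write_sto(
        trial_to_table(trial),
        path,
        in_degrees=False,
        name=trial.subject_id,
        extra_header={
            "subject_id": trial.subject_id,
            "mass": format(trial.mass, ".17g"),
            "stride_period": format(trial.stride_period, ".17g"),
        },
    )


def read_trial(path) -> GaitTrial:
    """Load a trial written by :func:`write_trial` (waveforms are not recoverable)."""
    table, header = read_sto(path)
    try:
        mass = float(header["mass"])
        period = float(header["stride_period"])
    except KeyError as exc:
        raise StoFormatError(f"{path}: trial header missing {exc}") from exc
    angles, velocities, moments = {}, {}, {}
    for joint in JOINTS:
        for side in SIDES:
            tag = f"{joint}_{side[0]}"
            key = (joint, side)
            angles[key] = table[f"{tag}_angle"].to_numpy()
            velocities[key] = table[f"{tag}_speed"].to_numpy()
            moments[key] = table[f"{tag}_moment"].to_numpy()
    return GaitTrial(
        subject_id=header.get("subject_id", header.get("name", "unknown")),
        time=table["time"].to_numpy(),
        stride_period=period,
        mass=mass,
        angles=angles,
        velocities=velocities,
        moments=moments,
    )
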