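"""File formats: TRC marker trajectories, CSV tables, JSON sidecars.

TRC is the tab-delimited motion-capture interchange format (header with
DataRate/NumFrames/NumMarkers/Units, then Frame#, Time and X/Y/Z triplets
per marker).  Occluded frame-markers are written as empty fields, the
conventional representation of gaps.  All writers are atomic (temp file +
rename) so a failed run never leaves a partial table, and CSV/JSON
outputs carry a metadata header (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import Vertebra
from .mocap import MarkerTrajectory

__all__ = [
    "atomic_write_text",
    "write_trc",
    "read_trc",
    "write_csv",
    "read_csv",
    "write_json",
    "metadata_header",
    "config_hash",
]

_DECIMALS = 5  # printed precision of TRC coordinates, mm


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename; no partial files on failure."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(seed: int | None = None, extra: dict | None = None) -> str:
    """Comment-line metadata block for CSV outputs."""
    lines = [f"# cspine-version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _marker_name(vertebra: Vertebra, label: str) -> str:
    return f"{vertebra.value}_{label}"


def write_trc(traj: MarkerTrajectory, path: str | Path) -> None:
    """Write a trajectory as TRC (bit-exact for a given input)."""
    path = Path(path)
    names = [_marker_name(v, lb) for v, lb in traj.labels]
    n_frames, n_markers = traj.n_frames, traj.n_markers
    rate = traj.rate_hz
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n_frames}\t{n_markers}\tmm\t{rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t"
        + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(n_markers)
        ),
        "",
    ]
    times = traj.times
    for f in range(n_frames):
        fields = [str(f + 1), f"{times[f]:.{_DECIMALS}f}"]
        for m in range(n_markers):
            if traj.missing[f, m]:
                fields.extend(["", "", ""])
            else:
                fields.extend(
                    f"{traj.positions[f, m, ax]:.{_DECIMALS}f}" for ax in range(3)
                )
        lines.append("\t".join(fields))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_trc(path: str | Path) -> MarkerTrajectory:
    """Parse a TRC file; malformed lines raise with their line number."""
    path = Path(path)
    raw = path.read_text().splitlines()
    if len(raw) < 6:
        raise ValueError(f"{path}: truncated TRC file ({len(raw)} lines)")
    header_keys = raw[1].split("\t")
    header_vals = raw[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as err:
        raise ValueError(f"{path}: bad TRC header at line 3: {err}")
    if meta.get("Units", "mm") != "mm":
        raise ValueError(f"{path}: unsupported units {meta.get('Units')!r}")
    name_fields = raw[3].split("\t")[2:]
    names = [n for n in name_fields if n]
    if len(names) != n_markers:
        raise ValueError(
            f"{path}: line 4 lists {len(names)} marker names, header says "
            f"{n_markers}"
        )
    labels: list[tuple[Vertebra, str]] = []
    for n in names:
        v, _, lb = n.partition("_")
        try:
            labels.append((Vertebra(v), lb))
        except ValueError:
            raise ValueError(f"{path}: marker {n!r} has no vertebra prefix")
    positions = np.full((n_frames, n_markers, 3), np.nan)
    missing = np.zeros((n_frames, n_markers), dtype=bool)
    data_lines = [ln for ln in raw[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise ValueError(
            f"{path}: {len(data_lines)} data rows, header says {n_frames}"
        )
    for row, ln in enumerate(data_lines):
        fields = ln.split("\t")
        expected = 2 + 3 * n_markers
        if len(fields) > expected:
            raise ValueError(
                f"{path}: {len(fields)} fields at data line {row + 1} "
                f"(expected {expected})"
            )
        if len(fields) < expected:
            fields = fields + [""] * (expected - len(fields))
        try:
            int(fields[0])
            float(fields[1])
        except ValueError:
            raise ValueError(
                f"{path}: bad frame/time fields at data line {row + 1}"
            )
        for m in range(n_markers):
            trio = fields[2 + 3 * m : 5 + 3 * m]
            if any(t == "" for t in trio):
                missing[row, m] = True
                continue
            try:
                positions[row, m] = [float(t) for t in trio]
            except ValueError:
                raise ValueError(
                    f"{path}: bad coordinate at line {row + 7}, marker "
                    f"{names[m]}"
                )
    return MarkerTrajectory(
        rate_hz=rate, labels=labels, positions=positions, missing=missing
    )


def trajectory_to_frame(traj: MarkerTrajectory) -> pd.DataFrame:
    """Long-format CSV alternative: one row per frame-marker."""
    rows = []
    times = traj.times
    for f in range(traj.n_frames):
        for m, (v, lb) in enumerate(traj.labels):
            miss = bool(traj.missing[f, m])
            x, y, z = (
                (np.nan, np.nan, np.nan) if miss else tuple(traj.positions[f, m])
            )
            rows.append(
                {
                    "frame": f + 1,
                    "time_s": times[f],
                    "vertebra": v.value,
                    "marker": lb,
                    "x": x,
                    "y": y,
                    "z": z,
                    "missing": miss,
                }
            )
    return pd.DataFrame(rows)


def frame_to_trajectory(df: pd.DataFrame, rate_hz: float | None = None) -> MarkerTrajectory:
    """Inverse of :func:`trajectory_to_frame`."""
    if rate_hz is None:
        times = np.sort(df["time_s"].unique())
        if len(times) < 2:
            raise ValueError("cannot infer rate from a single frame")
        rate_hz = 1.0 / float(np.median(np.diff(times)))
    labels = [
        (Vertebra(v), lb)
        for v, lb in df[["vertebra", "marker"]].drop_duplicates().itertuples(
            index=False
        )
    ]
    frames = np.sort(df["frame"].unique())
    pos = np.full((len(frames), len(labels), 3), np.nan)
    miss = np.ones((len(frames), len(labels)), dtype=bool)
    col = {key: i for i, key in enumerate(labels)}
    frow = {f: i for i, f in enumerate(frames)}
    for rec in df.itertuples(index=False):
        i = frow[rec.frame]
        j = col[(Vertebra(rec.vertebra), rec.marker)]
        if not rec.missing:
            pos[i, j] = (rec.x, rec.y, rec.z)
            miss[i, j] = False
    return MarkerTrajectory(rate_hz=rate_hz, labels=labels, positions=pos, missing=miss)


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> None:
    """CSV with a commented metadata header, written atomically."""
    text = metadata_header(seed=seed, extra=extra_meta) + df.to_csv(index=False)
    atomic_write_text(path, text)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(
    obj,
    path: str | Path,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> None:
    """JSON with an embedded metadata block, written atomically."""
    payload = {
        "_meta": {
            "cspine_version": __version__,
            **({"seed": seed} if seed is not None else {}),
            **(extra_meta or {}),
        },
        **(obj if isinstance(obj, dict) else {"data": obj}),
    }
    atomic_write_text(path, json.dumps(payload, indent=2, default=str) + "\n")
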