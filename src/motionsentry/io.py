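"""File formats: motion CSV, skeleton JSON, modality/label CSVs, run configs.

Conventions used everywhere: 0-based joint and coordinate indices, times in
seconds, positions in meters, UTF-8, decimal points, snake_case JSON keys.
The motion CSV dialect is long format with header ``time,joint,x,y,z``
(``x,y`` for planar data), rows sorted by time then joint order; round-trips
are lossless to 1e-9 m.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusion import ModalityBundle
from .motion import MotionSequence, SkeletonGraph, build_graph

_AXES = ("x", "y", "z")
_PRECISION = 9  # decimal digits; 1e-9 m round-trip guarantee


class DataFormatError(ValueError):
    """A file violated the declared dialect; the message names the location."""


# ------------------------------------------------------------------- motion
def write_motion_csv(seq: MotionSequence, path) -> None:
    T, J, D = seq.positions.shape
    cols = list(_AXES[:D])
    rows = []
    for t in range(T):
        for j in range(J):
            rows.append(
                [round(float(seq.times[t]), _PRECISION), seq.joint_names[j]]
                + [round(float(v), _PRECISION) for v in seq.positions[t, j]]
            )
    df = pd.DataFrame(rows, columns=["time", "joint"] + cols)
    df.to_csv(path, index=False, float_format=f"%.{_PRECISION}f")


def read_motion_csv(path, vertical_axis: int = -1) -> MotionSequence:
    path = Path(path)
    df = pd.read_csv(path)
    header = list(df.columns)
    if header[:2] != ["time", "joint"] or header[2:] not in (
        ["x", "y"],
        ["x", "y", "z"],
    ):
        raise DataFormatError(
            f"{path.name}: header must be time,joint,x,y[,z]; got {header}"
        )
    coords = header[2:]
    for c in coords + ["time"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[coords + ["time"]].isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
        raise DataFormatError(f"{path.name}: malformed row at line {line}")
    times = np.sort(df["time"].unique())
    first = df[df["time"] == times[0]]
    joint_names = first["joint"].astype(str).tolist()
    J, D, T = len(joint_names), len(coords), len(times)
    order = {name: j for j, name in enumerate(joint_names)}
    if len(order) != J:
        raise DataFormatError(f"{path.name}: duplicate joint at the first timestamp")

    positions = np.full((T, J, D), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    prev_key = None
    for row_num, rec in enumerate(df.itertuples(index=False), start=2):
        t, joint = float(rec.time), str(rec.joint)
        if joint not in order:
            raise DataFormatError(
                f"{path.name}: line {row_num}: unknown joint {joint!r}"
            )
        key = (t_index[t], order[joint])
        if prev_key is not None and key <= prev_key:
            raise DataFormatError(
                f"{path.name}: line {row_num}: rows not sorted by time then joint"
            )
        prev_key = key
        positions[key] = [getattr(rec, c) for c in coords]
    missing = np.argwhere(np.isnan(positions[:, :, 0]))
    if missing.size:
        t_m, j_m = missing[0]
        raise DataFormatError(
            f"{path.name}: joint {joint_names[j_m]!r} missing at time {times[t_m]}"
        )
    try:
        return MotionSequence(
            times=times,
            positions=positions,
            joint_names=joint_names,
            vertical_axis=vertical_axis,
        )
    except ValueError as e:
        raise DataFormatError(f"{path.name}: {e}") from e


def impute_gaps(positions: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linear interpolation of interior NaN runs of length <= max_gap.

    Longer gaps, or gaps touching either end, reject the sequence.
    """
    out = positions.copy()
    T = out.shape[0]
    flat = out.reshape(T, -1)
    for c in range(flat.shape[1]):
        col = flat[:, c]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        if isnan[0] or isnan[-1]:
            raise DataFormatError("missing samples at a sequence boundary")
        idx = np.nonzero(isnan)[0]
        runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
        for run in runs:
            if len(run) > max_gap:
                raise DataFormatError(
                    f"gap of {len(run)} frames starting at frame {run[0]} "
                    f"exceeds the {max_gap}-frame interpolation limit"
                )
        good = ~isnan
        col[isnan] = np.interp(np.nonzero(isnan)[0], np.nonzero(good)[0], col[good])
    return out


# ----------------------------------------------------------------- skeleton
def write_skeleton_json(graph: SkeletonGraph, path) -> None:
    payload = {
        "joints": graph.joint_names
        or [f"joint_{i}" for i in range(graph.n_joints)],
        "edges": [list(e) for e in graph.edges],
        "masses": graph.masses.tolist(),
        "vertical_axis": 2,
        "sensor_map": graph.sensor_map,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_skeleton_json(path) -> SkeletonGraph:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    joints = payload["joints"]
    return build_graph(
        payload["edges"],
        len(joints),
        masses=payload.get("masses"),
        joint_names=joints,
        sensor_map=payload.get("sensor_map"),
    )


# --------------------------------------------------------------- modalities
def write_modality_csv(bundle: ModalityBundle, times: np.ndarray, path) -> None:
    """Long format `time,modality,channel,value`; channels are `j{j}_{k}`."""
    rows = []
    for name in bundle.names:
        arr = bundle.features[name]
        T, J, C = arr.shape
        for t in range(T):
            for j in range(J):
                for c in range(C):
                    rows.append(
                        [
                            round(float(times[t]), _PRECISION),
                            name,
                            f"j{j}_{c}",
                            round(float(arr[t, j, c]), _PRECISION),
                        ]
                    )
    pd.DataFrame(rows, columns=["time", "modality", "channel", "value"]).to_csv(
        path, index=False
    )


def read_modality_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("modality"):
        times = np.sort(grp["time"].unique())
        chans = sorted(
            grp["channel"].unique(), key=lambda s: tuple(map(int, s[1:].split("_")))
        )
        J = max(int(c[1:].split("_")[0]) for c in chans) + 1
        C = max(int(c.split("_")[1]) for c in chans) + 1
        arr = np.zeros((len(times), J, C))
        t_idx = {t: i for i, t in enumerate(times)}
        for rec in grp.itertuples(index=False):
            j, c = map(int, rec.channel[1:].split("_"))
            arr[t_idx[rec.time], j, c] = rec.value
        out[str(name)] = arr
    return out


# ------------------------------------------------------------------- labels
def write_labels_csv(labels, annotations, path) -> None:
    rows = []
    for i, (y, ann) in enumerate(zip(labels, annotations)):
        if ann is None:
            rows.append([i, int(y), "", "", ""])
        else:
            rows.append([i, int(y), ann.joint, ann.onset, ann.duration])
    pd.DataFrame(
        rows, columns=["sequence", "label", "joint", "onset", "duration"]
    ).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------------ configs
def read_config_yaml(path, known_keys: set[str] | None = None) -> dict:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(cfg, dict):
        raise DataFormatError(f"{path}: config must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise DataFormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    manifest = {
        "schema": 1,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
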