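"""Generic marker-trajectory I/O for motion-capture comparison.

Two plain-text formats are supported: TRC (the tab-separated marker
trajectory format used by most motion-capture pipelines) and a long-format
CSV with columns ``time_s, marker, x, y, z`` in meters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Trajectory


def write_trc(
    path: str | Path, names: list[str], data: np.ndarray, fps: float, units: str = "m"
) -> None:
    """Write marker trajectories (n_frames, n_markers, 3) as a TRC file."""
    data = np.asarray(data, dtype=float)
    n_frames, n_markers, _ = data.shape
    if len(names) != n_markers:
        raise ValueError("one name per marker required")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{fps:g}\t{fps:g}\t{n_frames}\t{n_markers}\t{units}\t{fps:g}\t1\t{n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_markers))
            + "\n\n"
        )
        for i in range(n_frames):
            row = [str(i + 1), f"{i / fps:.6f}"]
            row += [f"{v:.6f}" for v in data[i].ravel()]
            fh.write("\t".join(row) + "\n")


def read_trc(path: str | Path) -> tuple[list[str], np.ndarray, float]:
    """Read a TRC file; returns (marker names, (n_frames, n_markers, 3), fps)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = lines[2].split("\t")
    fps = float(meta[0])
    n_markers = int(meta[3])
    names = [n for n in lines[3].split("\t")[2:] if n][:n_markers]
    rows = []
    for line in lines[5:]:
        parts = line.split("\t")
        if len(parts) < 2 + 3 * n_markers or not parts[0].strip():
            continue
        rows.append([float(v) for v in parts[2 : 2 + 3 * n_markers]])
    data = np.asarray(rows).reshape(len(rows), n_markers, 3)
    return names, data, fps


def write_marker_csv(
    path: str | Path, names: list[str], data: np.ndarray, fps: float
) -> None:
    """Write markers as long-format CSV (time_s, marker, x, y, z)."""
    n_frames = data.shape[0]
    t = np.arange(n_frames) / fps
    frames = []
    for j, name in enumerate(names):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "marker": name,
                    "x": data[:, j, 0],
                    "y": data[:, j, 1],
                    "z": data[:, j, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_marker_csv(path: str | Path) -> tuple[list[str], np.ndarray, float]:
    """Read long-format marker CSV; time must be uniformly sampled."""
    table = pd.read_csv(path)
    names = list(dict.fromkeys(table["marker"]))
    t = np.sort(table["time_s"].unique())
    if t.size < 2:
        raise ValueError("need at least two time samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("marker CSV must be uniformly sampled")
    fps = 1.0 / float(dt[0])
    data = np.full((t.size, len(names), 3), np.nan)
    index = {v: i for i, v in enumerate(np.round(t, 9))}
    for j, name in enumerate(names):
        sub = table[table["marker"] == name]
        rows = [index[v] for v in np.round(sub["time_s"].to_numpy(), 9)]
        data[rows, j] = sub[["x", "y", "z"]].to_numpy()
    return names, data, fps


def marker_trajectory(
    names: list[str], data: np.ndarray, fps: float, marker: str, axis: int
) -> Trajectory:
    """Extract one marker's coordinate as a :class:`Trajectory`."""
    j = names.index(marker)
    return Trajectory(values=data[:, j, axis], fps=fps)
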