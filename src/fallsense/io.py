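"""Frame-stream and dataset-manifest serialization.

The frame-csv dialect stores one frame per row::

    timestamp,ambient,pir,p_r1c1,p_r1c2,...,p_r32c32

Pixels are row-major with one-based names, temperatures in decimal degrees
Celsius, UTF-8 with LF line endings.  A dataset directory holds one frame-csv
per scenario plus a ``manifest.csv`` with columns
(file, label, ambient_level, objective, illumination, speed, state, area,
scene, seed).

Floats are written with ``repr`` (shortest round-trip form), so
``read_stream(write_stream(s))`` reproduces canonical files byte-for-byte.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GRID_SHAPE, FrameStream, StreamFormatError, ThermalFrame

_N_PIX = GRID_SHAPE[0] * GRID_SHAPE[1]

HEADER = ["timestamp", "ambient", "pir"] + [
    f"p_r{r}c{c}"
    for r in range(1, GRID_SHAPE[0] + 1)
    for c in range(1, GRID_SHAPE[1] + 1)
]

MANIFEST_COLUMNS = [
    "file",
    "label",
    "ambient_level",
    "objective",
    "illumination",
    "speed",
    "state",
    "area",
    "scene",
    "seed",
]


def read_stream(path: str | Path, fs: float = 5.0) -> FrameStream:
    """Read a frame-csv file into a :class:`FrameStream`.

    Raises :class:`StreamFormatError` naming the offending row when a data
    row does not carry exactly 1024 pixel columns, and when timestamps are
    not strictly increasing.
    """
    path = Path(path)
    frames: list[ThermalFrame] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StreamFormatError(f"{path}: empty file") from None
        if header != HEADER:
            raise StreamFormatError(f"{path}: unexpected header line")
        for i, row in enumerate(reader, start=1):
            if len(row) != 3 + _N_PIX:
                raise StreamFormatError(
                    f"{path}: data row {i} has {len(row) - 3} pixel columns, "
                    f"expected {_N_PIX}"
                )
            try:
                ts = float(row[0])
                ambient = float(row[1])
                pir = int(row[2])
                grid = np.array(row[3:], dtype=np.float64).reshape(GRID_SHAPE)
            except ValueError as exc:
                raise StreamFormatError(f"{path}: data row {i}: {exc}") from None
            frames.append(ThermalFrame(grid, ambient, ts, pir))
    return FrameStream(frames, fs=fs)


def write_stream(stream: FrameStream, path: str | Path) -> Path:
    """Write a non-empty stream in the frame-csv dialect; returns the path."""
    if len(stream) == 0:
        raise StreamFormatError("cannot write an empty stream")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(HEADER) + "\n")
        for frame in stream:
            cells = [repr(frame.timestamp), repr(frame.ambient), str(frame.pir)]
            cells.extend(repr(v) for v in frame.grid.ravel().tolist())
            fh.write(",".join(cells) + "\n")
    return path


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS, lineterminator="\n")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise StreamFormatError(f"manifest missing columns: {sorted(missing)}")
    return df


def read_dataset(directory: str | Path, fs: float = 5.0):
    """Yield (FrameStream, manifest row) pairs for a dataset directory.

    Each returned stream carries the manifest's label and factor levels in
    ``scenario_meta``.
    """
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    for _, row in manifest.iterrows():
        stream = read_stream(directory / row["file"], fs=fs)
        stream.label = row["label"]
        stream.scenario_meta = {
            "ambient_c": float(row["ambient_level"]),
            "objective": row["objective"],
            "illumination": row["illumination"],
            "speed": row["speed"],
            "state": row["state"],
            "area": row["area"],
            "scene": row["scene"],
        }
        yield stream, row
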