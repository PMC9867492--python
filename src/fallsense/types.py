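"""Shared domain types for the thermal fall-detection pipeline.

The sensing unit is a low-resolution thermopile array that reports a 32x32
grid of absolute temperatures (degrees Celsius) plus one ambient-temperature
reading per frame, sampled at a nominal 5 Hz.  A co-mounted pyroelectric
(PIR) motion sensor contributes one binary activity level per frame.

Pixel coordinates are one-based throughout: row ``r`` (1..32) increases
downward in the image and column ``c`` (1..32) increases rightward, so a
falling person's centroid moves toward larger ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRID_SHAPE = (32, 32)
DEFAULT_FS = 5.0

#: Factor levels of the scenario design (ambient in degC; the rest two-level).
AMBIENT_LEVELS = (18.0, 21.0, 24.0, 27.0, 30.0)
OBJECTIVE_LEVELS = ("female_160", "male_180")
ILLUMINATION_LEVELS = ("led", "sunlight")
SPEED_LEVELS = ("fast", "slow")
STATE_LEVELS = ("sitting", "lying")
AREA_LEVELS = ("boundary", "center")
SCENE_LEVELS = ("shower", "no_shower")
LABEL_LEVELS = ("fall", "non_fall")

SCENARIO_FACTORS = (
    "ambient_c",
    "objective",
    "illumination",
    "speed",
    "state",
    "area",
    "scene",
)


class StreamFormatError(ValueError):
    """Raised when a frame stream file or stream object violates the format."""


@dataclass(eq=False)
class ThermalFrame:
    """One thermopile frame: temperature grid, ambient reading, PIR level.

    ``pir`` is the raw sensor level; the 2-second hold that turns it into the
    SPIR activity signal is applied downstream by the detector, so stored
    data stays raw.
    """

    grid: np.ndarray
    ambient: float
    timestamp: float
    pir: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != GRID_SHAPE:
            raise StreamFormatError(
                f"frame grid must be {GRID_SHAPE}, got {self.grid.shape}"
            )
        if self.pir not in (0, 1):
            raise StreamFormatError(f"pir must be 0 or 1, got {self.pir!r}")
        self.ambient = float(self.ambient)
        self.timestamp = float(self.timestamp)
        self.pir = int(self.pir)

    def pixel(self, r: int, c: int) -> float:
        """Temperature at one-based (row, column)."""
        if not (1 <= r <= GRID_SHAPE[0] and 1 <= c <= GRID_SHAPE[1]):
            raise IndexError(f"one-based pixel index out of range: ({r}, {c})")
        return float(self.grid[r - 1, c - 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ThermalFrame):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and self.ambient == other.ambient
            and self.timestamp == other.timestamp
            and self.pir == other.pir
        )


@dataclass(eq=False)
class FrameStream:
    """An ordered sequence of frames with sampling rate and optional truth.

    ``label`` is the ground-truth class of the whole stream ('fall' or
    'non_fall'); ``scenario_meta`` carries the factor levels of the scenario
    design when the stream came from the simulator or a dataset manifest.
    """

    frames: list[ThermalFrame] = field(default_factory=list)
    fs: float = DEFAULT_FS
    label: str | None = None
    scenario_meta: dict | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise StreamFormatError(f"fs must be positive, got {self.fs}")
        if self.label is not None and self.label not in LABEL_LEVELS:
            raise StreamFormatError(f"label must be one of {LABEL_LEVELS}")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise StreamFormatError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, idx: int) -> ThermalFrame:
        return self.frames[idx]

    def __eq__(self, other: object) -> bool:
        """Data-model equality: frames and sampling rate (metadata is carried
        by the dataset manifest and compared there)."""
        if not isinstance(other, FrameStream):
            return NotImplemented
        return (
            self.fs == other.fs
            and len(self.frames) == len(other.frames)
            and all(a == b for a, b in zip(self.frames, other.frames))
        )
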