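"""Shared fixtures.

The two dataset-level fixtures run the full 640-scenario factorial through
the detector (noise-free and at the default sensor noise) once per session;
several end-to-end tests share them.  Streams are generated at 30 s, long
enough for the rendered activities to complete and the fall rule to mature.
"""

from __future__ import annotations

import numpy as np
import pytest

from fallsense import extract_dataset_features, scenario_grid
from fallsense.types import FrameStream, ThermalFrame

BASE_SEED = 1
EVAL_DURATION_S = 30.0


def make_frame(fill=25.0, ambient=24.0, timestamp=0.0, pir=0, patches=()):
    """A 32x32 frame filled with `fill`; `patches` are ((r0, r1, c0, c1), temp)
    one-based inclusive row/col ranges painted at `temp`."""
    grid = np.full((32, 32), float(fill))
    for (r0, r1, c0, c1), temp in patches:
        grid[r0 - 1:r1, c0 - 1:c1] = temp
    return ThermalFrame(grid, ambient, timestamp, pir)


def constant_stream(n=10, fill=25.0, fs=5.0, pir=0):
    frames = [make_frame(fill, timestamp=k / fs, pir=pir) for k in range(n)]
    return FrameStream(frames, fs=fs)


@pytest.fixture(scope="session")
def noisefree_features():
    grid = scenario_grid(BASE_SEED, noise_sigma=0.0, duration_s=EVAL_DURATION_S)
    return extract_dataset_features(grid)


@pytest.fixture(scope="session")
def noisy_features():
    grid = scenario_grid(BASE_SEED, noise_sigma=0.3, duration_s=EVAL_DURATION_S)
    return extract_dataset_features(grid)
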