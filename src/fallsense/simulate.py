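"""Synthetic bathroom scenes for the thermal + PIR fall-detection pipeline.

The simulator renders 32x32 absolute-temperature streams with the geometric
and statistical structure the detector assumes, over the full scenario
factor grid: five ambient temperatures (18-30 degC) crossed with two-level
factors for subject build, illumination, fall speed, post-fall state, fall
area and shower scene, each as a fall and a non-fall variant — a 640-stream
factorial (5 x 2^6 x 2).

Rendering model
---------------
* Background: ambient temperature plus an illumination term (LED: a mild
  cool vignette toward the corners; sunlight: a +2 degC horizontal ramp)
  plus i.i.d. Gaussian sensor noise (default sigma 0.3 degC, the scale of a
  typical thermopile NETD).
* Body: an elliptical blob between 33 degC (rim) and 36 degC (core),
  composited with ``max``.  Pre-fall semi-axes are (6, 4) pixels for the
  shorter subject and (8, 5) for the taller one, chosen so the locked pixel
  count sits inside the (20, 200) plausibility band of the fall rule.
* Falls translate the blob centroid down by more than half its row span and
  shrink its area to a ratio inside (0.5, 1) — about 0.85 when ending
  sitting, 0.6 when ending lying — over 0.5 s (fast) or a sustained 2.5 s
  (slow).  Falls are preceded by a short sideways stagger (the slip) and
  followed by 2 s of sub-pixel settling motion; the body then lies still
  and the raw PIR level decays to 0.
* Non-falls cycle through four archetypes keyed to the factor levels:
  squat-and-rise (small centroid drop, below the fall rule's displacement
  bound), a horizontal walk-through, a normal shower (person present with
  continuous small motion beside the water patch), and shower-only with no
  person.
* Shower scenes add a static warm water patch that is rendered either at
  35 degC — inside the body temperature band, so it is confusable with a
  person — or above 40 degC (removed by abnormal-pixel rejection), chosen by
  the scenario seed, plus a few residual warm floor pixels.
* Raw PIR is 1 on frames where the rendered body centroid moved by at least
  0.5 px (and on appearance frames); it is never driven by the static water
  patch.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .types import (
    AMBIENT_LEVELS, AREA_LEVELS, DEFAULT_FS, GRID_SHAPE, ILLUMINATION_LEVELS,
    LABEL_LEVELS, OBJECTIVE_LEVELS, SCENE_LEVELS, SPEED_LEVELS, STATE_LEVELS,
    FrameStream, ThermalFrame,
)

BODY_RIM_C = 33.0
BODY_CORE_C = 36.0
BODY_AXES = {"female_160": (6.0, 4.0), "male_180": (8.0, 5.0)}  # (row, col) semi-axes
POST_FALL_RATIO = {"sitting": 0.85, "lying": 0.6}
POST_FALL_ROW_SCALE = {"sitting": 0.7, "lying": 0.5}
FALL_DROP_ROWS = {"female_160": 12.0, "male_180": 12.0}
PRE_FALL_ROW = {"female_160": 9.0, "male_180": 10.0}
PRE_FALL_COL = {"boundary": 6.0, "center": 16.0}
FALL_ONSET_S = 10.0
WALK_IN_END_S = 2.5
PATCH_CENTER = (27.0, 28.0)
PATCH_RADIUS = 2.5
PIR_MOTION_PX = 0.5

_ROWS, _COLS = np.meshgrid(
    np.arange(1, GRID_SHAPE[0] + 1, dtype=np.float64),
    np.arange(1, GRID_SHAPE[1] + 1, dtype=np.float64),
    indexing="ij",
)


@dataclass
class ScenarioConfig:
    """One cell of the scenario factor grid plus generation parameters."""

    ambient_c: float
    objective: str
    illumination: str
    speed: str
    state: str
    area: str
    scene: str
    label: str
    noise_sigma: float = 0.3
    seed: int = 0
    duration_s: float = 120.0
    fs: float = DEFAULT_FS

    def __post_init__(self):
        checks = [
            (self.ambient_c, AMBIENT_LEVELS, "ambient_c"),
            (self.objective, OBJECTIVE_LEVELS, "objective"),
            (self.illumination, ILLUMINATION_LEVELS, "illumination"),
            (self.speed, SPEED_LEVELS, "speed"),
            (self.state, STATE_LEVELS, "state"),
            (self.area, AREA_LEVELS, "area"),
            (self.scene, SCENE_LEVELS, "scene"),
            (self.label, LABEL_LEVELS, "label"),
        ]
        for value, levels, name in checks:
            if value not in levels:
                raise ValueError(f"{name} must be one of {levels}, got {value!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        # durations shorter than the scripted activities simply truncate
        # the stream; the rendered truth still reports the full geometry

    def factors(self) -> dict:
        return {
            "ambient_c": self.ambient_c, "objective": self.objective,
            "illumination": self.illumination, "speed": self.speed,
            "state": self.state, "area": self.area, "scene": self.scene,
        }


@dataclass
class ScenarioTruth:
    """Ground truth of the rendered geometry, for tests and gating."""

    fall_time_s: float | None       # fall onset, None for non-falls
    fall_complete_s: float | None
    expected_rnc: float | None      # rendered post/pre pixel-count ratio
    expected_dsyc_ratio: float | None  # rendered |dSYc| / LY


def _ellipse_mask(cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    d2 = ((_ROWS - cy) / ry) ** 2 + ((_COLS - cx) / rx) ** 2
    return d2 <= 1.0


def _background(config: ScenarioConfig) -> np.ndarray:
    bg = np.full(GRID_SHAPE, config.ambient_c, dtype=np.float64)
    if config.illumination == "sunlight":
        bg += 2.0 * (_COLS - 1.0) / (GRID_SHAPE[1] - 1)
    else:  # led: mild cool vignette toward the corners
        d = np.hypot((_ROWS - 16.5) / 16.0, (_COLS - 16.5) / 16.0)
        bg -= 0.3 * d
    return bg


def _fall_progress(t: np.ndarray, speed: str) -> tuple[np.ndarray, float]:
    """Normalized descent progress p(t) in [0, 1] and the completion time."""
    t0 = FALL_ONSET_S
    if speed == "fast":
        end = t0 + 0.5
        p = np.clip((t - t0) / 0.5, 0.0, 1.0)
    else:
        # continuous constant-rate descent over 2.5 s: the sustained
        # centroid creep keeps the stability std above its bound all the
        # way down, so no intermediate stable snapshot fragments the
        # before/after comparison (a slow fall that pauses stably half-way
        # is genuinely outside what the adjacent-stable-moment rule can
        # span — see the methods note)
        end = t0 + 2.5
        p = np.clip((t - t0) / 2.5, 0.0, 1.0)
    return p, end


def _person_trajectory(config: ScenarioConfig, rng: np.random.Generator,
                       t: np.ndarray):
    """Per-frame (present, cy, cx, ry, rx) arrays plus the scenario truth."""
    n = t.size
    ry0, rx0 = BODY_AXES[config.objective]
    present = np.ones(n, dtype=bool)
    cy = np.full(n, PRE_FALL_ROW[config.objective])
    cx = np.full(n, PRE_FALL_COL[config.area])
    ry = np.full(n, ry0)
    rx = np.full(n, rx0)

    def walk_in():
        entry = PRE_FALL_COL[config.area] - 8.0
        m = t < WALK_IN_END_S
        cx[m] = entry + (PRE_FALL_COL[config.area] - entry) * t[m] / WALK_IN_END_S

    if config.label == "fall":
        walk_in()
        # slip precursor: an out-and-back sideways stagger in the final
        # 1.2 s before the fall.  Real falls are preceded by motion; this
        # breaks centroid stability before the fall, so the last stable
        # reference snapshot is frozen while the body is still settled
        # rather than refreshed on the cooling afterimage of the old
        # position during the fall transient
        stag = (t >= FALL_ONSET_S - 1.2) & (t < FALL_ONSET_S)
        cx[stag] += 3.0 * np.sin(np.pi * (t[stag] - (FALL_ONSET_S - 1.2)) / 1.2)
        p, complete = _fall_progress(t, config.speed)
        dy = FALL_DROP_ROWS[config.objective]
        sr = POST_FALL_ROW_SCALE[config.state]
        sc = POST_FALL_RATIO[config.state] / sr
        cy += p * dy
        cx += p * 1.0  # small sideways drift, well inside the LY/3 bound
        ry *= 1.0 + p * (sr - 1.0)
        rx *= 1.0 + p * (sc - 1.0)
        # settling micro-motion for 2 s after impact (limbs coming to rest):
        # sub-pixel jitter that keeps the PIR channel active without
        # breaking centroid stability
        settle = (t >= complete) & (t < complete + 2.0)
        cy[settle] += rng.uniform(-0.6, 0.6, size=int(settle.sum()))
        cx[settle] += rng.uniform(-0.6, 0.6, size=int(settle.sum()))
        pre = _ellipse_mask(PRE_FALL_ROW[config.objective],
                            PRE_FALL_COL[config.area], ry0, rx0)
        post = _ellipse_mask(PRE_FALL_ROW[config.objective] + dy,
                             PRE_FALL_COL[config.area] + 1.0,
                             ry0 * sr, rx0 * sc)
        pre_rows = np.nonzero(pre)[0]
        post_rows = np.nonzero(post)[0]
        span = pre_rows.max() - pre_rows.min() + 1
        truth = ScenarioTruth(
            fall_time_s=FALL_ONSET_S, fall_complete_s=complete,
            expected_rnc=post.sum() / pre.sum(),
            expected_dsyc_ratio=abs(post_rows.mean() - pre_rows.mean()) / span,
        )
        return present, cy, cx, ry, rx, truth

    truth = ScenarioTruth(None, None, None, None)
    activity = _nonfall_activity(config)
    if activity == "squat_and_rise":
        walk_in()
        t0 = FALL_ONSET_S
        drop, hold, rise = 0.8, 1.5, 0.8
        p = np.zeros(n)
        p[(t >= t0) & (t < t0 + drop)] = (t[(t >= t0) & (t < t0 + drop)] - t0) / drop
        p[(t >= t0 + drop) & (t < t0 + drop + hold)] = 1.0
        m = (t >= t0 + drop + hold) & (t < t0 + drop + hold + rise)
        p[m] = 1.0 - (t[m] - (t0 + drop + hold)) / rise
        cy += p * 4.0  # centroid drop well below the LY/2 fall bound
        ry *= 1.0 + p * (0.85 - 1.0)
        rx *= 1.0 + p * (0.941 - 1.0)
    elif activity == "walk_through":
        row = 8.0 if config.area == "boundary" else 14.0
        cy[:] = row
        motion_s = 6.0 if config.speed == "fast" else 12.0
        pause_s = 1.5
        start, stop = -6.0, 38.0
        v = (stop - start) / motion_s
        t_pause = 1.0 + (16.0 - start) / v  # pause when reaching mid-room
        cxx = np.full(n, start)
        for k, tk in enumerate(t):
            if tk < 1.0:
                present[k] = False
            elif tk < t_pause:
                cxx[k] = start + v * (tk - 1.0)
            elif tk < t_pause + pause_s:
                cxx[k] = 16.0
            else:
                cxx[k] = 16.0 + v * (tk - t_pause - pause_s)
                if cxx[k] > stop:
                    present[k] = False
        cx[:] = cxx
    elif activity == "normal_shower":
        present[:] = t >= 1.0
        anchor = np.array([12.0, PRE_FALL_COL[config.area]])
        pos = anchor.copy()
        for k in range(n):
            step = rng.normal(0.0, 0.3, size=2) - 0.1 * (pos - anchor)
            pos = np.clip(pos + step, anchor - 2.0, anchor + 2.0)
            cy[k], cx[k] = pos
    else:  # shower_only: no person at all
        present[:] = False
    return present, cy, cx, ry, rx, truth


def _nonfall_activity(config: ScenarioConfig) -> str:
    if config.scene == "no_shower":
        return "squat_and_rise" if config.state == "sitting" else "walk_through"
    return "normal_shower" if config.state == "sitting" else "shower_only"


def generate_scenario(config: ScenarioConfig) -> tuple[FrameStream, ScenarioTruth]:
    """Render one labeled scenario; bit-identical for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    bg = _background(config)

    present, cy, cx, ry, rx, truth = _person_trajectory(config, rng, t)

    patch_temps = None
    patch_start = 0.0
    if config.scene == "shower":
        hot = rng.random() < 0.5  # above-40 variant exercises abnormal rejection
        patch_c = 43.0 if hot else 35.0
        d2 = (((_ROWS - PATCH_CENTER[0]) ** 2 + (_COLS - PATCH_CENTER[1]) ** 2)
              / PATCH_RADIUS ** 2)
        patch_temps = np.where(d2 <= 1.0, patch_c - 1.0 * d2, -np.inf)
        if _nonfall_activity(config) == "shower_only" and config.label == "non_fall":
            patch_start = 4.0
        # residual warm floor pixels
        rr = rng.integers(20, 32, size=4)
        rc = rng.integers(1, 32, size=4)
        residual = (rr, rc)
    else:
        residual = None

    frames = []
    prev_cent = None
    for k in range(n):
        grid = bg.copy()
        if config.noise_sigma > 0:
            grid += rng.normal(0.0, config.noise_sigma, size=GRID_SHAPE)
        if residual is not None:
            grid[residual[0] - 1, residual[1] - 1] = np.maximum(
                grid[residual[0] - 1, residual[1] - 1], config.ambient_c + 2.5
            )
        if patch_temps is not None and t[k] >= patch_start:
            grid = np.maximum(grid, patch_temps)
        pir = 0
        if present[k]:
            d2 = (((_ROWS - cy[k]) / ry[k]) ** 2
                  + ((_COLS - cx[k]) / rx[k]) ** 2)
            body = BODY_RIM_C + (BODY_CORE_C - BODY_RIM_C) * (1.0 - d2)
            grid = np.where(d2 <= 1.0, np.maximum(grid, body), grid)
            if prev_cent is None:
                pir = 1  # appearance is a flux change
            elif math.hypot(cy[k] - prev_cent[0],
                            cx[k] - prev_cent[1]) >= PIR_MOTION_PX:
                pir = 1
            prev_cent = (cy[k], cx[k])
        else:
            prev_cent = None
        frames.append(ThermalFrame(grid, config.ambient_c, t[k], pir))

    stream = FrameStream(frames, fs=config.fs, label=config.label,
                         scenario_meta=config.factors())
    return stream, truth


def scenario_grid(base_seed: int, *, noise_sigma: float = 0.3,
                  duration_s: float = 120.0, fs: float = DEFAULT_FS
                  ) -> list[ScenarioConfig]:
    """The full 640-scenario factorial with deterministically derived seeds.

    5 ambient levels x 2^6 binary-factor combinations x {fall, non-fall}
    = 640 scenarios: 128 per ambient level, 64 falls and 64 non-falls per
    level.  Two base seeds yield grids differing only in the per-scenario
    seeds.
    """
    words = np.random.SeedSequence(int(base_seed)).generate_state(640)
    configs = []
    i = 0
    for ambient in AMBIENT_LEVELS:
        for obj, ill, spd, st, ar, sc in product(
            OBJECTIVE_LEVELS, ILLUMINATION_LEVELS, SPEED_LEVELS,
            STATE_LEVELS, AREA_LEVELS, SCENE_LEVELS,
        ):
            for label in LABEL_LEVELS:
                configs.append(ScenarioConfig(
                    ambient_c=ambient, objective=obj, illumination=ill,
                    speed=spd, state=st, area=ar, scene=sc, label=label,
                    noise_sigma=noise_sigma,
                    seed=int(words[i] % (2 ** 31)),
                    duration_s=duration_s, fs=fs,
                ))
                i += 1
    return configs


def generate_dataset(base_seed: int, out_dir: str | Path, *,
                     noise_sigma: float = 0.3, duration_s: float = 120.0,
                     fs: float = DEFAULT_FS) -> pd.DataFrame:
    """Write the full factorial dataset (640 frame-csv files + manifest).

    Returns the manifest as a DataFrame; it is also written to
    ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, config in enumerate(scenario_grid(
            base_seed, noise_sigma=noise_sigma, duration_s=duration_s, fs=fs)):
        stream, _ = generate_scenario(config)
        fname = f"scenario_{i:04d}.csv"
        fio.write_stream(stream, out_dir / fname)
        rows.append({
            "file": fname, "label": config.label,
            "ambient_level": config.ambient_c, "objective": config.objective,
            "illumination": config.illumination, "speed": config.speed,
            "state": config.state, "area": config.area, "scene": config.scene,
            "seed": config.seed,
        })
    manifest = pd.DataFrame(rows, columns=fio.MANIFEST_COLUMNS)
    fio.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
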