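"""Streaming kinematic feature extraction and rule-based fall-action logic.

Per frame, the locked body region yields a centroid (Xc, Yc) = (mean column,
mean row).  Over the latest five frames (one second at 5 Hz) the detector
keeps centroid means and standard deviations; a frame is a *stable moment*
when

    stdXc < 1  and  stdYc < 1  and  |dXc| < 2  and  |dYc| < 2

with (dXc, dYc) the centroid step since the previous frame.  At stable
moments the stable center (SXc, SYc) = (mXc, mYc), the full temperature
grid, the locked-area mean temperature Tc, pixel count Nc and row span LY
are snapshotted; a snapshot whose center moved by more than a small shift
threshold from the current one becomes a *new* stable moment, and the pair
of adjacent stable snapshots drives fall recognition.

A fall action is declared (flag_act = 1) when, between adjacent stable
moments,

    |dTc| < 2 degC,  0.5 < RNc < 1,  20 < Nc < 200,
    |dSXc| < LY/3,   |dSYc| > LY/2,  SPIR == 1,
    1 < SXc < 30,    ED > 10,        flag_sta == 1

where RNc = Nc_new / Nc_old, LY is the previous snapshot's row span, ED is
the root of summed squared per-pixel temperature differences over the new
locked region (a genuinely new posture differs from residual heat, which
yields ED below 10), and SPIR is the PIR activity level extended by a
2-second hold.  On the 0 -> 1 transition Tc and Nc are latched as Tc0/Nc0
and the duration timer td starts.

The action resets (flag_act = 0, td cleared) when any of

    |dXc| > 2,  |dYc| > 2,  td > 120 s,
    Tc - Tc0 > 2 degC,  Nc - Nc0 > Nc0 / 3

holds: renewed center motion means the person is moving (squatting, getting
up), and one-sided growth of temperature or area means the lock drifted onto
hot water or another heat source.

Every frame emits the 8-element feature vector
[stdXc, stdYc, td, tbm, stdNc, stdTc, flag_sta, flag_act], where tbm is the
number of seconds with SPIR == 1 inside the trailing 60-second window and
stdNc/stdTc are one-second standard deviations of the per-frame locked-area
count and mean temperature.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import LockedRegion, segment
from .filtering import FilterCoefficients, design_lpf
from .types import FrameStream, ThermalFrame

FEATURE_NAMES = (
    "std_xc", "std_yc", "td", "tbm", "std_nc", "std_tc", "flag_sta", "flag_act",
)

CENTER_BUFFER_LEN = 5          # one second at fs = 5 Hz
PIR_HOLD_S = 2.0               # SPIR hold after raw activity
TBM_WINDOW_S = 60.0            # body-movement accumulation window
TD_MAX_S = 120.0               # fall-action auto-reset duration


@dataclass
class FeatureVector:
    std_xc: float
    std_yc: float
    td: float
    tbm: float
    std_nc: float
    std_tc: float
    flag_sta: int
    flag_act: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.std_xc, self.std_yc, self.td, self.tbm,
             self.std_nc, self.std_tc, self.flag_sta, self.flag_act],
            dtype=np.float64,
        )


@dataclass
class CenterTrack:
    """Rolling centroid statistics over the last five frames."""

    xc: float = math.nan
    yc: float = math.nan
    dxc: float = 0.0
    dyc: float = 0.0
    buffer: deque = None
    std_xc: float = 0.0
    std_yc: float = 0.0
    m_xc: float = math.nan
    m_yc: float = math.nan

    def __post_init__(self):
        if self.buffer is None:
            self.buffer = deque(maxlen=CENTER_BUFFER_LEN)

    def full(self) -> bool:
        return len(self.buffer) == CENTER_BUFFER_LEN


@dataclass
class StableSnapshot:
    """State of the locked area at a stable moment.

    Like the stable center (the one-second buffer means mXc/mYc), ``t_mean``
    and ``n_pix`` are one-second means of the per-frame locked-area mean
    temperature and pixel count: a single smeared frame at the edge of a
    stability window (the filtered image blends old and new body positions
    during a posture change) would otherwise corrupt the reference values
    the fall rule compares against.
    """

    sx: float              # SXc (column axis)
    sy: float              # SYc (row axis, downward positive)
    grid: np.ndarray       # full 32x32 temperature copy
    t_mean: float          # Tc, one-second mean
    n_pix: float           # Nc, one-second mean
    row_span: int          # LY


def update_center(region: LockedRegion, track: CenterTrack,
                  ddof: int = 0) -> CenterTrack:
    """Push the region centroid into the rolling track.

    ``ddof=0`` selects the population standard deviation over the buffer
    (the default estimator throughout the detector).
    """
    xc, yc = region.centroid()
    track.dxc = 0.0 if math.isnan(track.xc) else xc - track.xc
    track.dyc = 0.0 if math.isnan(track.yc) else yc - track.yc
    track.xc, track.yc = xc, yc
    track.buffer.append((xc, yc))
    xs = np.array([p[0] for p in track.buffer])
    ys = np.array([p[1] for p in track.buffer])
    track.m_xc = float(xs.mean())
    track.m_yc = float(ys.mean())
    if len(xs) > ddof:
        track.std_xc = float(xs.std(ddof=ddof))
        track.std_yc = float(ys.std(ddof=ddof))
    else:
        track.std_xc = track.std_yc = 0.0
    return track


def check_stability(track: CenterTrack) -> int:
    """flag_sta: 1 iff the rolling buffer is full and all four bounds hold
    (strict inequalities; stdXc == 1 exactly is unstable)."""
    if not track.full():
        return 0
    return int(
        track.std_xc < 1.0 and track.std_yc < 1.0
        and abs(track.dxc) < 2.0 and abs(track.dyc) < 2.0
    )


def euclidean_distance(old: StableSnapshot, new: StableSnapshot,
                       region: LockedRegion) -> float:
    """ED between adjacent stable snapshots over the locked region."""
    r = region.rows - 1
    c = region.cols - 1
    diff = new.grid[r, c] - old.grid[r, c]
    return float(np.sqrt(np.sum(diff * diff)))


def fall_action_condition(
    prev: StableSnapshot, curr: StableSnapshot, ed: float, spir: int,
    flag_sta: int, signed: bool = False,
) -> bool:
    """The nine-way conjunction that sets flag_act.

    ``signed=True`` uses the literal one-sided printed differences for
    dTc/dSXc/dSYc instead of absolute values.
    """
    d_tc = curr.t_mean - prev.t_mean
    d_sx = curr.sx - prev.sx
    d_sy = curr.sy - prev.sy
    if not signed:
        d_tc, d_sx, d_sy = abs(d_tc), abs(d_sx), abs(d_sy)
    if prev.n_pix <= 0:
        return False
    rnc = curr.n_pix / prev.n_pix
    ly = prev.row_span
    return (
        d_tc < 2.0
        and 0.5 < rnc < 1.0
        and 20 < curr.n_pix < 200
        and d_sx < ly / 3.0
        and d_sy > ly / 2.0
        and spir == 1
        and 1.0 < curr.sx < 30.0
        and ed > 10.0
        and flag_sta == 1
    )


def reset_condition(dxc: float, dyc: float, td: float,
                    tc: float, nc: float, tc0: float, nc0: float) -> bool:
    """The disjunction that clears flag_act.

    Center-motion terms use absolute values; the temperature and area terms
    are one-sided growth checks as printed.
    """
    return (
        abs(dxc) > 2.0
        or abs(dyc) > 2.0
        or td > TD_MAX_S
        or tc - tc0 > 2.0
        or nc - nc0 > nc0 / 3.0
    )


class FallDetector:
    """The per-frame state machine fusing segmentation with the PIR channel.

    Parameters
    ----------
    fs : sampling rate in Hz.
    std_ddof : delta degrees of freedom of the rolling standard deviations
        (0 = population, the default).
    stable_shift_min : minimum center shift (grid units) for a stable frame
        to open a *new* stable moment rather than refresh the current one; a
        continuously stable body therefore does not self-compare every
        frame.  The default matches the |dXc|, |dYc| < 2 motion bound of
        the stability test: sub-pixel drift while a settled body's filtered
        image finishes converging is the same stable moment, not a new one.
    snapshot_tc_std_max : thermal-stability gate on snapshot updates (degC).
        A stable snapshot is only taken when the one-second std of the
        locked-area mean temperature is below this bound.  Center stability
        alone is not enough: when a body leaves its position, the low-pass
        filter keeps a cooling afterimage there whose centroid does not move
        — without the thermal gate that afterimage would keep refreshing the
        reference snapshot with a collapsing Tc and break the before/after
        temperature comparison of the fall rule.
    signed_deltas : use one-sided printed differences in the fall-action
        conjunction instead of absolute values.
    merge_fixpoint : iterate the relation merge to a fixpoint (default) or
        keep the literal single pass.
    """

    def __init__(self, fs: float = 5.0, *, std_ddof: int = 0,
                 stable_shift_min: float = 2.0,
                 snapshot_tc_std_max: float = 1.0,
                 signed_deltas: bool = False,
                 merge_fixpoint: bool = True):
        if fs <= 0:
            raise ValueError("fs must be positive")
        self.fs = fs
        self.std_ddof = std_ddof
        self.stable_shift_min = stable_shift_min
        self.snapshot_tc_std_max = snapshot_tc_std_max
        self.signed_deltas = signed_deltas
        self.merge_fixpoint = merge_fixpoint
        self.track = CenterTrack()
        self.prev_stable: StableSnapshot | None = None
        self.curr_stable: StableSnapshot | None = None
        self.flag_sta = 0
        self.flag_act = 0
        self.td = 0.0
        self.tc0 = math.nan
        self.nc0 = math.nan
        self.pir_hold = 0
        self.spir_window: deque = deque(maxlen=int(round(TBM_WINDOW_S * fs)))
        self.nc_buf: deque = deque(maxlen=CENTER_BUFFER_LEN)
        self.tc_buf: deque = deque(maxlen=CENTER_BUFFER_LEN)

    # -- PIR channel -------------------------------------------------------

    def update_pir(self, raw_pir: int) -> int:
        """Extend raw PIR activity by a 2-second hold and accumulate tbm."""
        spir = 1 if (raw_pir == 1 or self.pir_hold > 0) else 0
        if raw_pir == 1:
            self.pir_hold = int(round(PIR_HOLD_S * self.fs))
        elif self.pir_hold > 0:
            self.pir_hold -= 1
        self.spir_window.append(spir)
        return spir

    @property
    def tbm(self) -> float:
        """Seconds of SPIR activity inside the trailing 60-second window."""
        return sum(self.spir_window) / self.fs

    # -- buffer statistics -------------------------------------------------

    def _buf_std(self, buf: deque) -> float:
        if len(buf) <= self.std_ddof:
            return 0.0
        return float(np.std(np.array(buf, dtype=np.float64), ddof=self.std_ddof))

    # -- main step ---------------------------------------------------------

    def step(self, frame: ThermalFrame) -> FeatureVector:
        """Consume one *filtered* frame and emit the feature vector."""
        spir = self.update_pir(frame.pir)
        region = segment(frame, to_fixpoint=self.merge_fixpoint)

        if region is None:
            # lock lost: clear the rolling buffers, decay flags; stable
            # snapshots are retained so a re-acquired lock can still compare
            self.track = CenterTrack()
            self.nc_buf.clear()
            self.tc_buf.clear()
            self.flag_sta = 0
            self.flag_act = 0
            self.td = 0.0
            return FeatureVector(0.0, 0.0, 0.0, self.tbm, 0.0, 0.0, 0, 0)

        update_center(region, self.track, ddof=self.std_ddof)
        nc_now = region.count
        tc_now = float(frame.grid[region.rows - 1, region.cols - 1].mean())
        self.nc_buf.append(nc_now)
        self.tc_buf.append(tc_now)

        self.flag_sta = check_stability(self.track)
        thermally_stable = self._buf_std(self.tc_buf) < self.snapshot_tc_std_max
        if self.flag_sta and thermally_stable:
            snap = StableSnapshot(
                sx=self.track.m_xc, sy=self.track.m_yc,
                grid=frame.grid.copy(),
                t_mean=float(np.mean(self.tc_buf)),
                n_pix=float(np.mean(self.nc_buf)),
                row_span=region.row_span,
            )
            if self.curr_stable is None:
                self.curr_stable = snap
            elif math.hypot(snap.sx - self.curr_stable.sx,
                            snap.sy - self.curr_stable.sy) > self.stable_shift_min:
                self.prev_stable = self.curr_stable
                self.curr_stable = snap
            else:
                self.curr_stable = snap  # refresh in place

        # the fall rule is re-evaluated at every stable frame: the filtered
        # temperatures of a freshly occupied area keep settling for a couple
        # of seconds, so a condition that fails at the first stable moment
        # can legitimately pass a few frames later while SPIR is still held
        if (self.flag_act == 0 and self.flag_sta
                and self.prev_stable is not None):
            ed = euclidean_distance(self.prev_stable, self.curr_stable, region)
            if fall_action_condition(self.prev_stable, self.curr_stable, ed,
                                     spir, self.flag_sta,
                                     signed=self.signed_deltas):
                self.flag_act = 1
                self.td = 0.0
                self.tc0 = self.curr_stable.t_mean
                self.nc0 = self.curr_stable.n_pix

        if self.flag_act == 1:
            self.td += 1.0 / self.fs
            tc_ref = self.curr_stable.t_mean if self.curr_stable else tc_now
            nc_ref = self.curr_stable.n_pix if self.curr_stable else nc_now
            if reset_condition(self.track.dxc, self.track.dyc, self.td,
                               tc_ref, nc_ref, self.tc0, self.nc0):
                self.flag_act = 0
                self.td = 0.0

        return FeatureVector(
            std_xc=self.track.std_xc, std_yc=self.track.std_yc,
            td=self.td, tbm=self.tbm,
            std_nc=self._buf_std(self.nc_buf),
            std_tc=self._buf_std(self.tc_buf),
            flag_sta=self.flag_sta, flag_act=self.flag_act,
        )

    def process(self, stream: FrameStream, *, prefiltered: bool = False,
                coeffs: FilterCoefficients | None = None) -> pd.DataFrame:
        """Run the full pipeline on a stream; one feature row per frame."""
        from .filtering import filter_stream

        if not prefiltered:
            stream = filter_stream(stream, coeffs or design_lpf(fs=stream.fs))
        rows = [self.step(f).as_array() for f in stream]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def stream_summary(features: pd.DataFrame) -> pd.Series:
    """Collapse per-frame features to the single per-test feature vector.

    The representative frame is the one with maximal fall-action duration td
    (the most developed fall evidence); if no frame ever had flag_act set,
    the final frame stands for the whole test.
    """
    if len(features) == 0:
        raise ValueError("empty feature frame")
    if features["td"].max() > 0:
        idx = features["td"].idxmax()
    else:
        idx = features.index[-1]
    return features.loc[idx]
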