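"""The streaming detector: center statistics, stability, ED, fall rule, PIR."""

import numpy as np
import pytest

from fallsense import FallDetector, ScenarioConfig, generate_scenario
from fallsense.features import (
    CenterTrack, StableSnapshot, check_stability, euclidean_distance,
    fall_action_condition, reset_condition, stream_summary, update_center,
)
from fallsense.filtering import filter_stream
from fallsense.segmentation import LockedRegion, segment

from conftest import make_frame


def region_of(pixels):
    rows = np.array([p[0] for p in pixels], dtype=np.int32)
    cols = np.array([p[1] for p in pixels], dtype=np.int32)
    return LockedRegion(rows=rows, cols=cols, label=1, count=len(pixels),
                        row_span=int(rows.max() - rows.min() + 1),
                        col_span=int(cols.max() - cols.min() + 1))


def snapshot(sx=16.0, sy=10.0, grid=None, t_mean=34.0, n_pix=70, row_span=12):
    if grid is None:
        grid = np.full((32, 32), 24.0)
    return StableSnapshot(sx=sx, sy=sy, grid=grid, t_mean=t_mean,
                          n_pix=n_pix, row_span=row_span)


# -- center tracking -------------------------------------------------------

def test_center_of_2x2_block():
    track = update_center(region_of([(5, 7), (5, 8), (6, 7), (6, 8)]),
                          CenterTrack())
    assert (track.xc, track.yc) == (7.5, 5.5)


def test_constant_center_has_zero_std_and_is_stable():
    track = CenterTrack()
    for _ in range(5):
        update_center(region_of([(10, 20)]), track)
    assert track.std_xc == track.std_yc == 0.0
    assert check_stability(track) == 1


def test_drifting_center_std_matches_closed_form():
    # +1 row per frame: population std of {y..y+4} is sqrt(2)
    track = CenterTrack()
    for k in range(5):
        update_center(region_of([(10 + k, 20)]), track)
    assert track.std_yc == pytest.approx(np.sqrt(2.0))
    assert track.std_xc == 0.0


def test_stability_boundaries_are_strict():
    t = CenterTrack()
    t.buffer.extend([(0, 0)] * 5)
    t.std_xc, t.std_yc, t.dxc, t.dyc = 0.5, 0.5, 0.0, 0.0
    assert check_stability(t) == 1
    t.std_xc = 1.0
    assert check_stability(t) == 0
    t.std_xc, t.dyc = 0.5, 3.0
    assert check_stability(t) == 0
    t.dyc = -3.0  # prose: absolute values of the center steps
    assert check_stability(t) == 0


def test_partial_buffer_is_never_stable():
    track = update_center(region_of([(10, 20)]), CenterTrack())
    assert check_stability(track) == 0


# -- Euclidean temperature distance ---------------------------------------

def test_ed_identical_grids_is_zero():
    s = snapshot()
    assert euclidean_distance(s, s, region_of([(5, 5)])) == 0.0


def test_ed_single_pixel_difference():
    old = snapshot()
    new = snapshot(grid=old.grid.copy())
    new.grid[4, 4] += 3.0
    assert euclidean_distance(old, new, region_of([(5, 5)])) == pytest.approx(3.0)


def test_ed_matches_bruteforce_double_loop():
    rng = np.random.default_rng(8)
    old = snapshot(grid=rng.uniform(15, 35, (32, 32)))
    new = snapshot(grid=rng.uniform(15, 35, (32, 32)))
    pix = {(int(r), int(c))
           for r, c in rng.integers(1, 33, size=(40, 2))}
    region = region_of(sorted(pix))
    acc = 0.0
    for r, c in region.pixels:
        acc += (new.grid[r - 1, c - 1] - old.grid[r - 1, c - 1]) ** 2
    assert euclidean_distance(old, new, region) == pytest.approx(np.sqrt(acc))


# -- PIR hold and movement time -------------------------------------------

def test_single_pir_pulse_holds_eleven_frames():
    det = FallDetector(fs=5.0)
    spir = [det.update_pir(1)] + [det.update_pir(0) for _ in range(15)]
    assert spir[:11] == [1] * 11
    assert spir[11:] == [0] * 5


def test_quiet_pir_keeps_tbm_zero():
    det = FallDetector(fs=5.0)
    for _ in range(50):
        det.update_pir(0)
    assert det.tbm == 0.0


def test_tbm_clamps_at_sixty_seconds():
    det = FallDetector(fs=5.0)
    for _ in range(450):  # 90 s of continuous activity
        det.update_pir(1)
    assert det.tbm == 60.0


# -- fall-action set and reset rules --------------------------------------

def fall_pair():
    prev = snapshot(sx=16.0, sy=9.0, t_mean=34.0, n_pix=70, row_span=12)
    curr = snapshot(sx=16.5, sy=16.5, t_mean=34.5, n_pix=49, row_span=6)
    return prev, curr


def test_fall_conjunction_passes_on_constructed_pair():
    prev, curr = fall_pair()
    assert fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)


@pytest.mark.parametrize("override,value", [
    ("ed", 5.0),            # re-appearing area exclusion: ED must exceed 10
    ("spir", 0),
    ("flag_sta", 0),
])
def test_fall_conjunction_fails_on_guard(override, value):
    prev, curr = fall_pair()
    kwargs = dict(ed=12.0, spir=1, flag_sta=1)
    kwargs[override] = value
    assert not fall_action_condition(prev, curr, **kwargs)


def test_fall_conjunction_open_intervals():
    prev, curr = fall_pair()
    curr.n_pix = prev.n_pix  # RNc == 1.0: no shrink, open interval
    assert not fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)
    prev, curr = fall_pair()
    curr.n_pix = 20  # Nc bound is strict
    assert not fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)
    prev, curr = fall_pair()
    curr.t_mean = prev.t_mean + 2.5
    assert not fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)
    prev, curr = fall_pair()
    curr.sx = 30.5  # stable center too close to the column boundary
    assert not fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)


def test_fall_conjunction_uses_absolute_displacements():
    prev, curr = fall_pair()
    curr.sy = prev.sy - 7.5  # upward jump of the same magnitude
    assert fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1)
    assert not fall_action_condition(prev, curr, ed=12.0, spir=1, flag_sta=1,
                                     signed=True)


def test_reset_rule_clauses():
    base = dict(dxc=0.0, dyc=0.0, td=10.0, tc=34.0, nc=60, tc0=34.0, nc0=60)
    assert not reset_condition(**base)
    assert reset_condition(**{**base, "td": 121.0})
    assert reset_condition(**{**base, "nc": 81})        # 21 > 60/3
    assert not reset_condition(**{**base, "nc": 79})    # 19 < 20
    assert reset_condition(**{**base, "tc": 36.5})
    assert not reset_condition(**{**base, "tc": 31.0})  # one-sided growth
    assert reset_condition(**{**base, "dyc": -2.5})     # absolute center step


# -- end-to-end stepping ---------------------------------------------------

def test_background_stream_never_raises_fall_action():
    det = FallDetector(fs=5.0)
    for k in range(30):
        fv = det.step(make_frame(fill=24.0, timestamp=k / 5.0))
        assert fv.flag_act == 0 and fv.td == 0.0


def test_lost_lock_clears_flags_and_buffers():
    det = FallDetector(fs=5.0)
    for k in range(10):
        det.step(make_frame(fill=20.0, timestamp=k / 5.0,
                            patches=(((10, 12, 10, 12), 34.0),)))
    fv = det.step(make_frame(fill=60.0, timestamp=2.0))  # saturated frame
    assert fv.flag_sta == 0 and fv.flag_act == 0 and fv.td == 0.0
    assert len(det.track.buffer) == 0


def fall_config(**over):
    base = dict(ambient_c=24.0, objective="female_160", illumination="led",
                speed="fast", state="lying", area="center", scene="no_shower",
                label="fall", noise_sigma=0.0, seed=3, duration_s=25.0)
    base.update(over)
    return ScenarioConfig(**base)


def test_simulated_fall_sets_flag_within_three_seconds():
    stream, truth = generate_scenario(fall_config())
    feats = FallDetector().process(stream)
    act = feats.index[feats["flag_act"] == 1]
    assert len(act) > 0
    assert act[0] / 5.0 <= truth.fall_complete_s + 3.0
    # td is nondecreasing within each contiguous fall-action episode
    flag = feats["flag_act"].to_numpy()
    td = feats["td"].to_numpy()
    inside = (flag[1:] == 1) & (flag[:-1] == 1)
    assert np.all(np.diff(td)[inside] >= 0)
    assert np.all(td[flag == 0] == 0.0)


def test_simulated_squat_never_sets_flag():
    cfg = fall_config(label="non_fall", state="sitting", duration_s=25.0)
    stream, _ = generate_scenario(cfg)
    feats = FallDetector().process(stream)
    assert feats["flag_act"].sum() == 0
    assert feats["flag_sta"].sum() > 0  # the squat pause does go stable


def test_detector_is_deterministic():
    stream, _ = generate_scenario(fall_config(noise_sigma=0.3))
    f1 = FallDetector().process(stream)
    f2 = FallDetector().process(stream)
    assert f1.equals(f2)


def test_stream_summary_prefers_longest_fall_action():
    stream, _ = generate_scenario(fall_config())
    feats = FallDetector().process(stream)
    s = stream_summary(feats)
    assert s["flag_act"] == 1
    assert s["td"] == feats["td"].max()
    quiet, _ = generate_scenario(fall_config(label="non_fall", state="lying",
                                             scene="no_shower"))
    fq = FallDetector().process(quiet)
    assert stream_summary(fq)["td"] == 0.0
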