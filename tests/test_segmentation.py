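"""Thresholding and double-boundary-scan labeling, against a flood-fill oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fallsense.segmentation import (
    first_scan, label_mask, merge_blocks, merge_relations, segment,
    select_largest, threshold_frame,
)

from conftest import make_frame

EIGHT = np.ones((3, 3), dtype=int)


def oracle_components(mask):
    """8-connected components via scipy flood fill: list of pixel-index sets."""
    lab, n = ndimage.label(mask, structure=EIGHT)
    return [set(zip(*np.nonzero(lab == i))) for i in range(1, n + 1)]


def region_pixels_zero_based(region):
    return set(zip((region.rows - 1).tolist(), (region.cols - 1).tolist()))


# -- thresholding ----------------------------------------------------------

def test_threshold_patch_example():
    f = make_frame(fill=20.0, patches=(((10, 12, 10, 12), 34.0),))
    m = threshold_frame(f)
    assert (m.t_min, m.t_max, m.t_th) == (20.0, 34.0, 27.0)
    assert m.selected.sum() == 9


def test_abnormal_pixels_never_selected_nor_extreme():
    f = make_frame(fill=20.0, patches=(((10, 12, 10, 12), 34.0),
                                       ((1, 1, 1, 1), 45.0),
                                       ((2, 2, 2, 2), -5.0)))
    m = threshold_frame(f)
    assert m.t_max == 34.0 and m.t_min == 20.0
    assert not m.selected[0, 0] and not m.selected[1, 1]


def test_uniform_grid_degenerates_to_full_selection():
    m = threshold_frame(make_frame(fill=22.0))
    assert m.t_th == m.t_max == m.t_min == 22.0
    assert m.selected.all()


def test_all_invalid_frame_yields_none():
    assert threshold_frame(make_frame(fill=60.0)) is None
    assert segment(make_frame(fill=60.0)) is None


# -- first scan ------------------------------------------------------------

def test_empty_mask_labels_nothing():
    g = first_scan(np.zeros((32, 32), bool))
    assert not g.labels.any() and g.relations == []


def test_diagonal_neighbor_inherits_label():
    m = np.zeros((32, 32), bool)
    m[4, 4] = m[5, 5] = True
    g = first_scan(m)
    assert g.labels[5, 5] == g.labels[6, 6] == 1  # bordered one-based index


def test_u_shape_records_one_relation():
    # two vertical arms joined only in the bottom row
    m = np.zeros((32, 32), bool)
    m[2:6, 2] = True
    m[2:6, 6] = True
    m[6, 2:7] = True
    g = first_scan(m)
    labels = set(g.labels[g.labels > 0].tolist())
    assert labels == {1, 2}
    # the junction is seen from two bottom-row pixels, one relation each
    assert set(g.relations) == {frozenset({1, 2})}
    merged = merge_blocks(g)
    assert set(merged.labels[merged.labels > 0].tolist()) == {1}


def test_border_stays_zero():
    m = np.ones((32, 32), bool)
    g = merge_blocks(first_scan(m))
    assert not g.labels[0].any() and not g.labels[-1].any()
    assert not g.labels[:, 0].any() and not g.labels[:, -1].any()


# -- relation merging ------------------------------------------------------

def test_chained_relations_merge_to_one_block():
    assert merge_relations([frozenset({3, 4}), frozenset({4, 5})]) == [{3, 4, 5}]


def test_single_pass_can_miss_chains_fixpoint_cannot():
    chain = [frozenset({1, 2}), frozenset({3, 4}), frozenset({2, 3})]
    assert {1, 2, 3, 4} in merge_relations(chain, to_fixpoint=True)
    assert {1, 2, 3, 4} not in merge_relations(chain, to_fixpoint=False)


def test_no_relations_is_identity():
    m = np.zeros((32, 32), bool)
    m[2, 2] = m[10, 10] = True
    g = merge_blocks(first_scan(m))
    assert g.counts == {1: 1, 2: 1}


# -- largest-block retention ----------------------------------------------

def test_largest_of_three_components_wins():
    m = np.zeros((32, 32), bool)
    m[1, 1:4] = True          # size 3
    m[5, 1:8] = True          # size 7
    m[10, 1:3] = True         # size 2
    region = select_largest(label_mask(m))
    assert region.count == 7
    assert region_pixels_zero_based(region) == {(5, c) for c in range(1, 8)}


def test_size_tie_breaks_to_smaller_block_number():
    m = np.zeros((32, 32), bool)
    m[1, 1:4] = True
    m[10, 10:13] = True
    region = select_largest(label_mask(m))
    assert region.count == 3
    assert region.label == 1
    assert region_pixels_zero_based(region) == {(1, c) for c in range(1, 4)}


def test_empty_grid_selects_none():
    assert select_largest(label_mask(np.zeros((32, 32), bool))) is None


# -- oracle equivalence and properties ------------------------------------

@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 2 ** 36 - 1))
def test_labeling_equals_floodfill_on_6x6(bits):
    m = np.array([(bits >> i) & 1 for i in range(36)], bool).reshape(6, 6)
    g = label_mask(m)
    comps = oracle_components(m)
    labels = g.labels[1:-1, 1:-1]
    # same partition: every component carries exactly one label
    for comp in comps:
        vals = {labels[r, c] for r, c in comp}
        assert len(vals) == 1 and 0 not in vals
    assert sorted(g.counts.values()) == sorted(len(c) for c in comps)


@pytest.mark.parametrize("seed", range(30))
def test_retained_region_is_maximal_component_32x32(seed):
    rng = np.random.default_rng(seed)
    m = rng.random((32, 32)) < rng.uniform(0.05, 0.6)
    region = select_largest(label_mask(m))
    comps = oracle_components(m)
    if not comps:
        assert region is None
        return
    best = max(len(c) for c in comps)
    assert region.count == best
    assert region_pixels_zero_based(region) in [c for c in comps if len(c) == best]


def test_label_partition_counts_selected_pixels():
    rng = np.random.default_rng(5)
    m = rng.random((32, 32)) < 0.4
    g = label_mask(m)
    assert sum(g.counts.values()) == int(m.sum())


def test_segment_is_idempotent_on_its_own_mask():
    f = make_frame(fill=20.0, patches=(((10, 12, 10, 12), 34.0),
                                       ((20, 24, 5, 8), 33.0),))
    region = segment(f)
    again = select_largest(label_mask(region.mask()))
    assert region_pixels_zero_based(again) == region_pixels_zero_based(region)


def test_segment_end_to_end_patch():
    f = make_frame(fill=20.0, patches=(((10, 12, 10, 12), 34.0),))
    region = segment(f)
    assert region.count == 9
    assert region.row_span == 3 and region.col_span == 3
    assert region.centroid() == (11.0, 11.0)
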