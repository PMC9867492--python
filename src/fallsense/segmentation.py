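"""Body localization in a filtered thermal frame.

The human body is the warmest extended object in a bathroom scene, so the
locator is threshold-based:

1. Abnormal-pixel rejection: readings above 40 degC or below 0 degC are
   physically implausible for a monitored body and are deleted before any
   statistics are taken (hot shower water can legitimately exceed 40 degC and
   is thereby removed).
2. Thresholding: with T_min and T_max the extremes over the remaining valid
   pixels, the threshold is their midpoint T_th = (T_min + T_max) / 2 and
   candidate pixels are those with T in the inclusive band [T_th, T_max].
3. Double boundary scan: a two-pass connected-component labeling over a
   34x34 zero-bordered label grid.  The first raster scan assigns provisional
   block numbers from the 8-neighborhood and records adjacency sets in a
   relationship table; the second pass unions intersecting sets and relabels
   each block to its set's minimum.
4. Largest-block retention: only the block with the greatest pixel count is
   kept ("locked"); everything else is treated as interference.

The selection band is inclusive at both ends: an exclusive upper bound would
discard the hottest pixel of the body itself.  When every valid temperature
is equal the degenerate threshold T_th = T_min = T_max selects all valid
pixels rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ThermalFrame

T_ABNORMAL_HIGH = 40.0
T_ABNORMAL_LOW = 0.0


@dataclass
class CandidateMask:
    """Thresholded candidate pixels of one frame plus the temperatures used."""

    selected: np.ndarray  # HxW bool
    t_min: float
    t_max: float
    t_th: float


@dataclass
class LabelGrid:
    """Zero-bordered label image plus the relationship table.

    ``labels`` has shape (H+2, W+2); interior cell [r, c] corresponds to the
    one-based frame pixel (r, c), so frame coordinates index it directly.
    ``counts`` is populated by :func:`merge_blocks` (labels are provisional
    after the first scan).
    """

    labels: np.ndarray
    relations: list[frozenset] = field(default_factory=list)
    counts: dict[int, int] | None = None


@dataclass
class LockedRegion:
    """The retained body block, in one-based frame coordinates."""

    rows: np.ndarray  # one-based row index per pixel
    cols: np.ndarray
    label: int
    count: int
    row_span: int  # max r - min r + 1
    col_span: int

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def mask(self, shape: tuple[int, int] = (32, 32)) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows - 1, self.cols - 1] = True
        return m

    def centroid(self) -> tuple[float, float]:
        """(mean column, mean row) = (Xc, Yc) in one-based grid units."""
        return float(self.cols.mean()), float(self.rows.mean())


def threshold_frame(frame: ThermalFrame) -> CandidateMask | None:
    """Reject abnormal pixels and threshold at the valid-range midpoint.

    Returns ``None`` when no valid pixel exists (e.g. a saturated frame).
    """
    grid = frame.grid
    valid = (grid >= T_ABNORMAL_LOW) & (grid <= T_ABNORMAL_HIGH)
    if not valid.any():
        return None
    vals = grid[valid]
    t_min = float(vals.min())
    t_max = float(vals.max())
    t_th = 0.5 * (t_min + t_max)
    selected = valid & (grid >= t_th) & (grid <= t_max)
    return CandidateMask(selected=selected, t_min=t_min, t_max=t_max, t_th=t_th)


def first_scan(mask: CandidateMask | np.ndarray) -> LabelGrid:
    """First boundary scan: provisional labels and the relationship table.

    Raster order (row-major, one-based).  For each candidate pixel the set P1
    of its 8 neighbors' labels is reduced to P2 by dropping zeros and
    duplicates; an empty P2 mints a fresh block number, otherwise the pixel
    takes min(P2), and |P2| > 1 appends P2 to the relationship table.  The
    zero border means unvisited and out-of-frame neighbors drop out without
    special-casing the scan direction.
    """
    sel = mask.selected if isinstance(mask, CandidateMask) else np.asarray(mask, bool)
    h, w = sel.shape
    # list-of-lists is measurably faster than ndarray indexing in this loop
    lab = [[0] * (w + 2) for _ in range(h + 2)]
    relations: list[frozenset] = []
    bn = 1
    rr, cc = np.nonzero(sel)
    for r0, c0 in zip(rr.tolist(), cc.tolist()):
        r, c = r0 + 1, c0 + 1
        up, mid, dn = lab[r - 1], lab[r], lab[r + 1]
        p2 = {up[c - 1], up[c], up[c + 1], mid[c - 1], mid[c + 1],
              dn[c - 1], dn[c], dn[c + 1]}
        p2.discard(0)
        if not p2:
            mid[c] = bn
            bn += 1
        else:
            mid[c] = min(p2)
            if len(p2) > 1:
                relations.append(frozenset(p2))
    return LabelGrid(labels=np.array(lab, dtype=np.int32), relations=relations)


def merge_relations(
    relations: list[frozenset], to_fixpoint: bool = True
) -> list[set]:
    """Union intersecting relation sets.

    The single pairwise pass of the original procedure can miss chains such
    as {1,2}, {3,4}, {2,3}; by default the pass is iterated to a fixpoint so
    the closure is transitive.  ``to_fixpoint=False`` keeps the literal
    single pass.
    """
    sets = [set(s) for s in relations]
    while True:
        changed = False
        for i in range(len(sets)):
            if not sets[i]:
                continue
            for j in range(i + 1, len(sets)):
                if sets[j] and sets[i] & sets[j]:
                    sets[i] |= sets[j]
                    sets[j] = set()
                    changed = True
        if not changed or not to_fixpoint:
            break
    return [s for s in sets if s]


def merge_blocks(grid: LabelGrid, to_fixpoint: bool = True) -> LabelGrid:
    """Second boundary scan: merge adjacent blocks and tally pixel counts.

    Every pixel whose label lies in a closed relation set is relabeled to the
    set's minimum; ``counts`` maps each surviving label to its pixel count.
    """
    labels = grid.labels.copy()
    merged = merge_relations(grid.relations, to_fixpoint=to_fixpoint)
    max_label = int(labels.max(initial=0))
    lut = np.arange(max_label + 1, dtype=labels.dtype)
    for s in merged:
        m = min(s)
        for lab in s:
            if lab <= max_label:
                lut[lab] = m
    labels = lut[labels]
    flat = np.bincount(labels.ravel(), minlength=1)
    counts = {int(lab): int(n) for lab, n in enumerate(flat) if lab > 0 and n > 0}
    return LabelGrid(labels=labels, relations=grid.relations, counts=counts)


def select_largest(grid: LabelGrid) -> LockedRegion | None:
    """Retain only the block with the greatest pixel count.

    Ties break toward the smallest block number (deterministic).  Returns
    ``None`` when no pixel is labeled.
    """
    if grid.counts is None:
        raise ValueError("select_largest requires a merged LabelGrid")
    if not grid.counts:
        return None
    best = max(grid.counts.items(), key=lambda kv: (kv[1], -kv[0]))
    label = min(lab for lab, n in grid.counts.items() if n == best[1])
    rr, cc = np.nonzero(grid.labels == label)
    # bordered index == one-based frame coordinate
    return LockedRegion(
        rows=rr.astype(np.int32),
        cols=cc.astype(np.int32),
        label=int(label),
        count=int(rr.size),
        row_span=int(rr.max() - rr.min() + 1),
        col_span=int(cc.max() - cc.min() + 1),
    )


def label_mask(mask: np.ndarray, to_fixpoint: bool = True) -> LabelGrid:
    """Full two-pass labeling of a binary mask (first scan + merge)."""
    return merge_blocks(first_scan(mask), to_fixpoint=to_fixpoint)


def segment(
    frame: ThermalFrame, to_fixpoint: bool = True
) -> LockedRegion | None:
    """Threshold, label, merge and retain the largest block of one frame."""
    mask = threshold_frame(frame)
    if mask is None:
        return None
    return select_largest(label_mask(mask.selected, to_fixpoint=to_fixpoint))


def labels_to_csv(grid: LabelGrid, path) -> None:
    """Debug writer: export a label grid as a CSV heat-map for inspection."""
    np.savetxt(path, grid.labels, fmt="%d", delimiter=",")
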