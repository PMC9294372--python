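"""Integration of per-trial label masks into one session-level mask.

ROIs found in different trials that correspond to the same cell are merged
with a capture-all strategy: the merged ROI is the pixel union of its
contributors, no trial ROI pixel is ever discarded, and ROIs seen in only
one trial are kept unchanged.  Two ROIs match when their pixel overlap is at
least ``overlap_fraction`` of the smaller ROI; matches are transitive
(resolved with union-find), so a chain A~B~C collapses to one session ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .core import LabelMask, ROI, mask_from_rois

__all__ = ["SessionMask", "merge_masks"]


@dataclass
class SessionMask:
    """A unified LabelMask plus, per ROI, its (source index, source ROI id) contributors."""

    mask: LabelMask
    provenance: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return self.mask.n_rois


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # anchor to the smaller root index for order-independent results
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _pixel_keys(pixels: np.ndarray, width: int) -> np.ndarray:
    return pixels[:, 0].astype(np.int64) * width + pixels[:, 1].astype(np.int64)


def merge_masks(
    masks: list[LabelMask],
    overlap_fraction: float = 0.3,
    mode: str = "overlap",
) -> SessionMask:
    """Merge trial (or session) masks into one capture-all session mask.

    Parameters
    ----------
    masks:
        Label masks sharing one frame shape.
    overlap_fraction:
        Two ROIs merge when their shared pixel count is at least this
        fraction of the smaller ROI's area (default 0.3).
    mode:
        ``"overlap"`` (default) merges by the fraction rule; ``"or"``
        binary-ORs all masks and relabels connected components, the simplest
        capture-all reading (adjacent distinct cells can fuse).

    The merged ROI keeps the highest contributor peak score; final ROIs are
    ordered deterministically by centroid (row, col) so the result does not
    depend on trial order.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("incompatible masks: shapes differ")

    if mode == "or":
        return _merge_or(masks, shape)
    if mode != "overlap":
        raise ValueError("mode must be 'overlap' or 'or'")

    entries = [
        (mi, roi) for mi, m in enumerate(masks) for roi in m.rois
    ]
    if not entries:
        return SessionMask(mask=LabelMask.empty(shape), provenance={})

    keys = [_pixel_keys(roi.pixels, shape[1]) for _, roi in entries]
    uf = _UnionFind(len(entries))
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if entries[i][0] == entries[j][0]:
                continue  # same source mask: never merge directly
            smaller = min(keys[i].size, keys[j].size)
            overlap = np.intersect1d(keys[i], keys[j], assume_unique=True).size
            if smaller > 0 and overlap >= overlap_fraction * smaller:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(uf.find(i), []).append(i)

    merged: list[tuple[ROI, list[tuple[int, int]]]] = []
    for members in groups.values():
        union_keys = np.unique(np.concatenate([keys[i] for i in members]))
        pixels = np.column_stack(np.divmod(union_keys, shape[1]))
        peak = max(entries[i][1].peak_score for i in members)
        contrib = sorted((entries[i][0], entries[i][1].id) for i in members)
        merged.append((ROI(id=0, pixels=pixels, peak_score=peak), contrib))

    merged.sort(key=lambda item: item[0].centroid)
    mask = mask_from_rois([roi for roi, _ in merged], shape)
    provenance = {roi.id: contrib for roi, (_, contrib) in zip(mask.rois, merged)}
    return SessionMask(mask=mask, provenance=provenance)


def _merge_or(masks: list[LabelMask], shape: tuple[int, int]) -> SessionMask:
    combined = np.zeros(shape, dtype=bool)
    for m in masks:
        combined |= m.labels > 0
        for roi in m.rois:  # pixel records may extend beyond the label image
            combined[roi.pixels[:, 0], roi.pixels[:, 1]] = True
    labels = cc_label(combined, connectivity=2)
    rois = []
    for lab in range(1, labels.max() + 1):
        rois.append(ROI(id=0, pixels=np.argwhere(labels == lab), peak_score=0.0))
    rois.sort(key=lambda r: r.centroid)
    mask = mask_from_rois(rois, shape)

    provenance: dict[int, list[tuple[int, int]]] = {roi.id: [] for roi in mask.rois}
    for mi, m in enumerate(masks):
        for roi in m.rois:
            hit = np.unique(mask.labels[roi.pixels[:, 0], roi.pixels[:, 1]])
            for h in hit[hit > 0]:
                provenance[int(h)].append((mi, roi.id))
    return SessionMask(mask=mask, provenance={k: sorted(v) for k, v in provenance.items()})
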