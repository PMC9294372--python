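"""Shared containers for trial-based calcium imaging analysis.

Conventions used throughout the package:

* Movies are ``T x H x W`` arrays of non-negative intensities (``ImageStack``).
* Shifts are signed integer ``(dx, dy)`` pairs where ``dx`` is the row offset
  and ``dy`` the column offset, 0-based; positive ``dx`` means the frame
  content sits ``dx`` rows below the template.
* Label masks are ``H x W`` integer images: 0 is background, ``k`` marks the
  pixels of ROI ``k``.  All coordinates in exported JSON are 0-based
  ``[row, col]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("trialcal")


class DegenerateFrameError(ValueError):
    """A constant (zero-variance) frame cannot be registered or thresholded."""


class InvalidOffsetError(ValueError):
    """An offset leaves no overlap between template and frame."""


@dataclass
class ImageStack:
    """A fluorescence movie: ``T`` frames of ``H x W`` intensities.

    Parameters
    ----------
    data:
        ``T x H x W`` array of finite, non-negative intensities.  Integer
        input is promoted to float64 for processing.
    fps:
        Acquisition rate in frames per second.
    pixel_size:
        Optional pixel pitch in micrometres, carried as metadata only.
    """

    data: np.ndarray
    fps: float = 15.0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise ValueError(f"expected T x H x W movie, got shape {data.shape}")
        t, h, w = data.shape
        if t < 1 or h < 8 or w < 8:
            raise ValueError(f"movie too small: T={t}, H={h}, W={w} (need T>=1, H,W>=8)")
        data = data.astype(np.float64, copy=False)
        if not np.all(np.isfinite(data)):
            raise ValueError("movie contains non-finite intensities")
        if data.min() < 0:
            raise ValueError("movie contains negative intensities")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.data = data

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame(self, index: int) -> np.ndarray:
        return self.data[index]


@dataclass
class TrialStructure:
    """Frame layout of one stimulus trial.

    ``baseline_frames`` are the pre-stimulus frames used for F0 / pixel
    statistics; by default the first ``round(fps)`` frames (1 s of baseline).
    The remaining frames form the response period.
    """

    n_frames: int
    fps: float = 15.0
    baseline_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a trial needs at least 2 frames")
        if self.baseline_frames is None:
            n_bl = min(int(round(self.fps)), self.n_frames - 1)
            self.baseline_frames = np.arange(max(n_bl, 1))
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=np.intp)
        if self.baseline_frames.size == 0:
            raise ValueError("baseline period must be non-empty")
        if self.baseline_frames.min() < 0 or self.baseline_frames.max() >= self.n_frames:
            raise ValueError("baseline frame indices out of range")

    @property
    def response_frames(self) -> np.ndarray:
        mask = np.ones(self.n_frames, dtype=bool)
        mask[self.baseline_frames] = False
        return np.flatnonzero(mask)


@dataclass
class ROI:
    """One region of interest: an 8-connected pixel set attributed to a cell."""

    id: int
    pixels: np.ndarray  # (n, 2) int array of [row, col]
    peak_score: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)

    @property
    def area(self) -> int:
        return self.pixels.shape[0]

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)


@dataclass
class LabelMask:
    """An ``H x W`` label image plus per-ROI records.

    ``labels`` holds 0 for background and the ROI id for labelled pixels.
    ROI ids start at 1 and are ordered by descending ``peak_score`` (ties by
    centroid row then column).
    """

    labels: np.ndarray
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LabelMask":
        return cls(labels=np.zeros(shape, dtype=np.int32), rois=[])


def mask_from_rois(rois: list[ROI], shape: tuple[int, int]) -> LabelMask:
    """Build a LabelMask from ROI records, renumbering ids 1..n.

    ROIs are painted in descending area order so that when unmerged ROIs
    share pixels the smaller ROI stays visible in the label image; the ROI
    pixel records remain authoritative either way.
    """
    labels = np.zeros(shape, dtype=np.int32)
    out: list[ROI] = []
    for new_id, roi in enumerate(rois, start=1):
        out.append(ROI(id=new_id, pixels=roi.pixels, peak_score=roi.peak_score))
    for roi in sorted(out, key=lambda r: -r.area):
        labels[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.id
    return LabelMask(labels=labels, rois=out)


def sort_rois(rois: list[ROI]) -> list[ROI]:
    """Order ROIs by descending peak score, ties by centroid (row, col)."""
    return sorted(rois, key=lambda r: (-r.peak_score, r.centroid[0], r.centroid[1]))
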