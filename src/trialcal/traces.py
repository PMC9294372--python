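"""Per-ROI dF/F trace extraction, activity classification, sorting and export.

For each ROI the raw trace ``F(t)`` is the mean intensity over the ROI's
pixels; the baseline ``F0`` is the mean of ``F(t)`` over the trial's baseline
frames; activity is ``F_activity(t) = (F(t) - F0) / F0``.  An ROI counts as
active when its peak activity exceeds the mean baseline activity by ``n_sd``
baseline standard deviations (default 5); alternative fixed-threshold and
minimum-size criteria are available.  Active ROIs are ranked by descending
peak dF/F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageStack, LabelMask, TrialStructure, logger

__all__ = ["TraceSet", "extract_traces", "classify_active", "sort_export"]


@dataclass
class TraceSet:
    """dF/F traces and classification state for a set of ROIs."""

    roi_ids: np.ndarray  # (n,) int, ids as in the source LabelMask
    f0: np.ndarray  # (n,) baseline fluorescence
    dff: np.ndarray  # (n, T) F_activity
    centroids: np.ndarray  # (n, 2) float, for deterministic tie-breaks
    fps: float = 15.0
    baseline_frames: np.ndarray = field(default_factory=lambda: np.arange(1))
    active: np.ndarray | None = None  # (n,) bool, set by classify_active

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    @property
    def peaks(self) -> np.ndarray:
        if self.dff.size == 0:
            return np.zeros(0)
        return self.dff.max(axis=1)


def extract_traces(
    stack: ImageStack,
    mask: LabelMask,
    trial: TrialStructure,
    eps: float = 1e-9,
) -> TraceSet:
    """Extract per-ROI dF/F traces from a registered trial movie.

    ROIs whose baseline fluorescence F0 is at or below ``eps`` are excluded
    (their dF/F is undefined) with a logged warning.
    """
    if mask.shape != stack.frame_shape:
        raise ValueError("mask and stack shapes differ")
    data = stack.data.reshape(stack.n_frames, -1)
    keep_ids, f0s, dffs, cents = [], [], [], []
    for roi in mask.rois:
        flat = roi.pixels[:, 0] * mask.shape[1] + roi.pixels[:, 1]
        f = data[:, flat].mean(axis=1)
        f0 = float(f[trial.baseline_frames].mean())
        if f0 <= eps:
            logger.warning("ROI %d excluded: baseline F0 = %.3g", roi.id, f0)
            continue
        keep_ids.append(roi.id)
        f0s.append(f0)
        dffs.append((f - f0) / f0)
        cents.append(roi.centroid)
    return TraceSet(
        roi_ids=np.asarray(keep_ids, dtype=np.int64),
        f0=np.asarray(f0s),
        dff=np.asarray(dffs).reshape(len(keep_ids), stack.n_frames),
        centroids=np.asarray(cents, dtype=np.float64).reshape(len(keep_ids), 2),
        fps=stack.fps,
        baseline_frames=np.asarray(trial.baseline_frames),
    )


def classify_active(
    traces: TraceSet,
    n_sd: float = 5.0,
    min_peak_dff: float | None = None,
    min_area: int | None = None,
    areas: np.ndarray | None = None,
) -> TraceSet:
    """Flag ROIs whose peak dF/F clears the baseline-noise criterion.

    Active means peak ``F_activity`` > mean + ``n_sd`` * SD of the ROI's own
    baseline-period ``F_activity`` (default 5 SD).  ``min_peak_dff`` adds a
    fixed dF/F floor and ``min_area`` (with ``areas``) a size floor; both are
    optional extra criteria.  Zero-SD baselines degenerate to mean + epsilon.
    """
    if traces.n_rois == 0:
        traces.active = np.zeros(0, dtype=bool)
        return traces
    bl = traces.dff[:, traces.baseline_frames]
    mu = bl.mean(axis=1)
    sd = bl.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("classify_active: %d zero-SD baselines use mean + eps", zero.sum())
    thr = np.where(zero, mu + 1e-12, mu + n_sd * sd)
    active = traces.peaks > thr
    if min_peak_dff is not None:
        active &= traces.peaks >= min_peak_dff
    if min_area is not None:
        if areas is None:
            raise ValueError("min_area requires per-ROI areas")
        active &= np.asarray(areas) >= min_area
    traces.active = active
    return traces


def sort_export(
    traces: TraceSet,
    top_n: int | None = None,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Rank ROIs (active first, descending peak dF/F) and optionally export.

    Ties in peak are broken by centroid (row, col) for stable output.
    Returns a summary DataFrame with columns ``roi, peak, active, rank``;
    when ``csv_path`` is given the full traces go there in long format
    (``roi, frame, dff``), and ``json_path`` receives the summary records.
    """
    active = (
        traces.active if traces.active is not None else np.ones(traces.n_rois, dtype=bool)
    )
    order = sorted(
        range(traces.n_rois),
        key=lambda i: (
            not active[i],
            -traces.peaks[i],
            traces.centroids[i, 0],
            traces.centroids[i, 1],
        ),
    )
    if top_n is not None:
        order = order[:top_n]
    summary = pd.DataFrame(
        {
            "roi": traces.roi_ids[order],
            "peak": traces.peaks[order],
            "active": active[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    if csv_path is not None:
        frames = np.arange(traces.dff.shape[1])
        long = pd.concat(
            [
                pd.DataFrame(
                    {"roi": traces.roi_ids[i], "frame": frames, "dff": traces.dff[i]}
                )
                for i in order
            ],
            ignore_index=True,
        ) if order else pd.DataFrame(columns=["roi", "frame", "dff"])
        long.to_csv(csv_path, index=False)
    if json_path is not None:
        records = summary.assign(
            peak=summary["peak"].astype(float), active=summary["active"].astype(bool)
        ).to_dict(orient="records")
        Path(json_path).write_text(json.dumps(records, indent=2))
    return summary
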