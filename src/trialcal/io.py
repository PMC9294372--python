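"""File formats: TIFF movies and label masks, CSV shifts/traces, JSON ROIs
and transforms, YAML run configuration.

All JSON coordinates are 0-based ``[row, col]`` — note that MATLAB-side
tooling in this field is 1-based, which is the number-one porting hazard
when exchanging ROI files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, LabelMask, ROI, logger
from .cross_session import PlanarTransform
from .session_mask import SessionMask

__all__ = [
    "read_stack",
    "write_stack",
    "write_mask",
    "read_mask",
    "write_shifts",
    "read_shifts",
    "write_transform",
    "read_transform",
    "RunConfig",
]


def read_stack(path: str | Path, fps: float = 15.0) -> ImageStack:
    """Read a grayscale multi-page TIFF movie into an ImageStack."""
    path = Path(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {data.shape} in {path.name}: expected a "
            "grayscale multi-page stack (RGB/planar images are not supported)"
        )
    return ImageStack(data.astype(np.float64), fps=fps)


def write_stack(stack: ImageStack, path: str | Path, dtype: str | None = None) -> None:
    """Write a movie as a multi-page TIFF (float64 unless a dtype is given)."""
    data = stack.data if dtype is None else stack.data.astype(dtype)
    tifffile.imwrite(Path(path), data)


def _paint_labels(rois: list[ROI], shape: tuple[int, int]) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int64)
    for roi in sorted(rois, key=lambda r: -r.area):
        labels[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.id
    return labels


def write_mask(
    mask: LabelMask | SessionMask,
    json_path: str | Path,
    tiff_path: str | Path | None = None,
) -> None:
    """Write a label mask as a JSON record (authoritative) plus optional label TIFF.

    The TIFF uses 16-bit labels, switching to 32-bit with a warning when ids
    overflow.  Session provenance, when present, is stored in the JSON.
    """
    provenance = None
    if isinstance(mask, SessionMask):
        provenance = {str(k): [list(c) for c in v] for k, v in mask.provenance.items()}
        mask = mask.mask
    record = {
        "shape": list(mask.shape),
        "rois": [
            {
                "id": roi.id,
                "pixels": roi.pixels.tolist(),
                "centroid": list(roi.centroid),
                "area": roi.area,
                "peak_dff": roi.peak_score,
            }
            for roi in mask.rois
        ],
    }
    if provenance is not None:
        record["provenance"] = provenance
    Path(json_path).write_text(json.dumps(record))
    if tiff_path is not None:
        max_id = max((roi.id for roi in mask.rois), default=0)
        if max_id > np.iinfo(np.uint16).max:
            logger.warning("label ids exceed 16-bit range; writing 32-bit label TIFF")
            tifffile.imwrite(Path(tiff_path), mask.labels.astype(np.uint32))
        else:
            tifffile.imwrite(Path(tiff_path), mask.labels.astype(np.uint16))


def read_mask(json_path: str | Path) -> LabelMask | SessionMask:
    """Read a mask written by :func:`write_mask`.

    Returns a SessionMask when provenance is present, a LabelMask otherwise.
    The label image is repainted from the pixel records (larger ROIs first),
    which reproduces the original exactly for non-overlapping ROIs.
    """
    record = json.loads(Path(json_path).read_text())
    shape = tuple(record["shape"])
    rois = [
        ROI(
            id=r["id"],
            pixels=np.asarray(r["pixels"], dtype=np.intp).reshape(-1, 2),
            peak_score=float(r["peak_dff"]),
        )
        for r in record["rois"]
    ]
    mask = LabelMask(labels=_paint_labels(rois, shape), rois=rois)
    if "provenance" in record:
        provenance = {
            int(k): [tuple(c) for c in v] for k, v in record["provenance"].items()
        }
        return SessionMask(mask=mask, provenance=provenance)
    return mask


def write_shifts(shifts: np.ndarray, path: str | Path) -> None:
    """Write per-frame shifts as CSV with columns frame, dx, dy."""
    shifts = np.asarray(shifts)
    pd.DataFrame(
        {"frame": np.arange(shifts.shape[0]), "dx": shifts[:, 0], "dy": shifts[:, 1]}
    ).to_csv(path, index=False)


def read_shifts(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["dx", "dy"]].to_numpy(dtype=np.int64)


def write_transform(tf: PlanarTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"kind": tf.kind, "matrix": tf.matrix.tolist()}, indent=2)
    )


def read_transform(path: str | Path) -> PlanarTransform:
    record = json.loads(Path(path).read_text())
    return PlanarTransform(np.asarray(record["matrix"]), kind=record["kind"])


_CONFIG_SECTIONS = {
    "fps": float,
    "frames_per_trial": int,
    "baseline_frames": int,
    "algorithm": int,
    "max_shift": (int, type(None)),
    "coarse_to_fine": bool,
    "overlap_fraction": float,
    "n_sd": float,
    "alg1": dict,
    "alg2": dict,
}


@dataclass
class RunConfig:
    """One-file YAML configuration for the whole pipeline.

    CLI flags override config values; unknown keys are rejected with a clear
    message so typos never silently fall back to defaults.
    """

    fps: float = 15.0
    frames_per_trial: int = 60
    baseline_frames: int = 15
    algorithm: int = 1
    max_shift: int | None = None
    coarse_to_fine: bool = False
    overlap_fraction: float = 0.3
    n_sd: float = 5.0
    alg1: dict = field(default_factory=dict)
    alg2: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(raw) - set(_CONFIG_SECTIONS)
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; "
                f"valid keys are {sorted(_CONFIG_SECTIONS)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
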