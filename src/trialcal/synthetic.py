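"""Ground-truth generators for testing the pipeline without real movies.

Two generators are provided:

* :func:`simulate_shifts` + :func:`build_shifted_movie` — movies corrupted by
  heartbeat-like periodic translations plus uniform jitter, with the true
  per-frame shifts kept as ground truth for registration accuracy checks.
* :func:`generate_cell_movie` — trial-structured movies of Gaussian-profile
  cells with baseline fluorescence, transient responses (instantaneous rise,
  exponential decay) and additive Gaussian read noise, with ground-truth
  masks and dF/F traces.

All stochastic functions take explicit seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack, LabelMask, ROI, TrialStructure, mask_from_rois
from .registration import apply_shift

__all__ = [
    "ShiftSimSpec",
    "CellMovieSpec",
    "simulate_shifts",
    "build_shifted_movie",
    "registration_error",
    "generate_cell_movie",
    "blob_field",
]


def blob_field(
    height: int,
    width: int,
    n_blobs: int = 30,
    seed: int | np.random.Generator = 0,
    margin: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Static field of Gaussian blobs over a dim background.

    A structured base image for registration and alignment fixtures: blob
    positions, widths (sigma 2-4 px) and amplitudes (50-150 over background
    20) are drawn from the seeded generator.  Returns the image and the
    (n, 2) blob centres.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr, cc = np.mgrid[0:height, 0:width]
    img = np.full((height, width), 20.0)
    centers = []
    for _ in range(n_blobs):
        r0 = rng.uniform(margin, height - margin)
        c0 = rng.uniform(margin, width - margin)
        sigma = rng.uniform(2.0, 4.0)
        amp = rng.uniform(50.0, 150.0)
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
        centers.append((r0, c0))
    return img, np.asarray(centers)


@dataclass
class ShiftSimSpec:
    """Parameters of the heartbeat-shift simulation.

    In each axis the shift of frame ``i`` (counted from 1) is the positive
    half-wave of a sinusoid of amplitude ``max_shift_*`` at ``heartbeat_rate``
    Hz, clipped to zero on the negative half-wave, plus uniform jitter drawn
    from ``[-jitter, jitter]``; the result is rounded to integer pixels.
    """

    n_frames: int = 300
    fps: float = 15.0
    max_shift_x: float = 10.0
    max_shift_y: float = 10.0
    jitter: float = 3.0
    heartbeat_rate: float = 1.0
    seed: int = 0


def simulate_shifts(spec: ShiftSimSpec) -> np.ndarray:
    """Generate a ``T x 2`` integer ground-truth shift series.

    Per axis and frame index ``i = 1..T``::

        s_i = round( rand(-Mr, Mr) )                       if sin(phi_i) <  0
        s_i = round( M * sin(phi_i) + rand(-Mr, Mr) )      if sin(phi_i) >= 0

    with phase ``phi_i = 2*pi*heartbeat_rate*i / fps``.  The x and y series
    are generated in the same manner with independent jitter draws.
    """
    rng = np.random.default_rng(spec.seed)
    i = np.arange(1, spec.n_frames + 1, dtype=np.float64)
    s = np.sin(2.0 * np.pi * spec.heartbeat_rate * i / spec.fps)
    shifts = np.zeros((spec.n_frames, 2), dtype=np.int64)
    for axis, m in enumerate((spec.max_shift_x, spec.max_shift_y)):
        jit = rng.uniform(-spec.jitter, spec.jitter, size=spec.n_frames)
        raw = np.where(s < 0, jit, m * s + jit)
        shifts[:, axis] = np.rint(raw).astype(np.int64)
    return shifts


def build_shifted_movie(base: np.ndarray, shifts: np.ndarray, fps: float = 15.0) -> ImageStack:
    """Compile a movie of copies of ``base``, each translated by its shift.

    Frame ``k`` holds the base image moved down/right by ``(dx_k, dy_k)``
    with edge-value fill, matching the sign convention of the registration
    module: registering the result against the unshifted base recovers the
    shift series exactly.
    """
    base = np.asarray(base, dtype=np.float64)
    shifts = np.asarray(shifts, dtype=np.int64)
    h, w = base.shape
    if np.abs(shifts).max(initial=0) >= min(h, w):
        raise ValueError("shift magnitude exceeds image size")
    frames = np.empty((shifts.shape[0], h, w))
    rows = np.arange(h)
    cols = np.arange(w)
    for k, (dx, dy) in enumerate(shifts):
        r = np.clip(rows - dx, 0, h - 1)
        c = np.clip(cols - dy, 0, w - 1)
        frames[k] = base[np.ix_(r, c)]
    return ImageStack(frames, fps=fps)


def registration_error(truth: np.ndarray, estimate: np.ndarray) -> tuple[float, float]:
    """Per-axis sum of squared shift differences, diff(t, e) = sum (t_i - e_i)^2."""
    truth = np.asarray(truth, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if truth.shape != estimate.shape:
        raise ValueError("truth and estimate must have equal length")
    err = ((truth - estimate) ** 2).sum(axis=0)
    return float(err[0]), float(err[1])


@dataclass
class CellMovieSpec:
    """A stated world for planted-cell trial movies.

    Defaults describe one 4-s trial at 15 fps (15 baseline frames) on a
    128x128 field with 8 Gaussian cells of sigma 3 px sitting 100 intensity
    units above a 100-unit background, all responsive with a dF/F transient
    of amplitude 0.5 (instantaneous rise at stimulus onset, exponential decay
    with tau = 10 frames) and additive read noise of SD 10 — i.e. a pixel-level
    baseline dF/F noise SD of about 0.1, so the planted transient sits at
    5x the noise floor.
    """

    height: int = 128
    width: int = 128
    n_cells: int = 8
    n_responsive: int | None = None  # default: all cells respond
    cell_radius: float = 3.0  # Gaussian sigma, px
    cell_amplitude: float = 100.0  # resting peak height above background
    baseline_level: float = 100.0
    transient_amplitude: float = 0.5  # ROI-mean dF/F at transient peak
    transient_onset: int | None = None  # default: first response frame
    decay_tau: float = 10.0  # frames
    noise_sd: float = 10.0
    trial: TrialStructure = field(default_factory=lambda: TrialStructure(n_frames=60, fps=15.0))
    seed: int = 0
    margin: float | None = None  # keep-out border, default 2*sigma + 2


def _place_cells(spec: CellMovieSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centres whose 2-sigma disks do not overlap."""
    margin = spec.margin if spec.margin is not None else 2 * spec.cell_radius + 2
    min_dist = 4 * spec.cell_radius
    centers: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centers) == spec.n_cells:
            break
        r = rng.uniform(margin, spec.height - margin)
        c = rng.uniform(margin, spec.width - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_dist**2 for rr, cc in centers):
            centers.append((r, c))
    else:
        raise RuntimeError(
            f"could not place {spec.n_cells} non-overlapping cells in "
            f"{spec.height}x{spec.width} after bounded rejection sampling"
        )
    return np.asarray(centers, dtype=np.float64).reshape(-1, 2)


def generate_cell_movie(
    spec: CellMovieSpec,
) -> tuple[ImageStack, LabelMask, dict[str, np.ndarray]]:
    """Generate a planted-cell trial movie with full ground truth.

    The resting image is ``baseline_level + sum_c A_c * G_c`` with Gaussian
    profiles ``G_c``.  Responsive cells add a transient whose spatial profile
    is the cell's own Gaussian, scaled so that the mean dF/F over the
    ground-truth ROI (pixels within 2 sigma of the centre) peaks exactly at
    ``transient_amplitude`` in the noise-free movie.  The temporal kernel is
    0 before ``transient_onset`` and ``exp(-(t - onset)/tau)`` after.

    Returns
    -------
    stack, mask, truth:
        The movie; the ground-truth label mask; a dict with ``centers``
        ((n, 2) float), ``responsive`` (bool per cell), ``dff`` (n x T
        ground-truth ROI dF/F traces) and ``onset``.
    """
    rng = np.random.default_rng(spec.seed)
    trial = spec.trial
    t_frames = trial.n_frames
    n_resp = spec.n_cells if spec.n_responsive is None else spec.n_responsive
    if n_resp > spec.n_cells:
        raise ValueError("n_responsive cannot exceed n_cells")
    onset = (
        spec.transient_onset
        if spec.transient_onset is not None
        else (int(trial.response_frames[0]) if spec.n_cells else 0)
    )

    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    rest = np.full((spec.height, spec.width), spec.baseline_level, dtype=np.float64)
    centers = (
        _place_cells(spec, rng) if spec.n_cells else np.zeros((0, 2), dtype=np.float64)
    )
    responsive = np.zeros(spec.n_cells, dtype=bool)
    responsive[:n_resp] = True

    profiles = []
    rois: list[ROI] = []
    for k in range(spec.n_cells):
        r0, c0 = centers[k]
        g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * spec.cell_radius**2))
        profiles.append(g)
        rest += spec.cell_amplitude * g
        in_roi = (rr - r0) ** 2 + (cc - c0) ** 2 <= (2 * spec.cell_radius) ** 2
        pix = np.argwhere(in_roi)
        rois.append(ROI(id=k + 1, pixels=pix, peak_score=0.0))

    kernel = np.zeros(t_frames)
    t = np.arange(t_frames)
    kernel[t >= onset] = np.exp(-(t[t >= onset] - onset) / spec.decay_tau)

    movie = np.repeat(rest[np.newaxis], t_frames, axis=0)
    dff_truth = np.zeros((spec.n_cells, t_frames))
    for k in range(spec.n_cells):
        if not responsive[k]:
            continue
        roi_idx = (rois[k].pixels[:, 0], rois[k].pixels[:, 1])
        g_roi = profiles[k][roi_idx]
        f0_roi = rest[roi_idx].mean()
        # scale so the ROI-mean dF/F peaks exactly at transient_amplitude
        scale = spec.transient_amplitude * f0_roi * rois[k].area / g_roi.sum()
        movie += (scale * profiles[k])[np.newaxis] * kernel[:, np.newaxis, np.newaxis]
        dff_truth[k] = spec.transient_amplitude * kernel
        rois[k].peak_score = spec.transient_amplitude * kernel.max()

    if spec.noise_sd > 0:
        movie = movie + rng.normal(0.0, spec.noise_sd, size=movie.shape)
        np.maximum(movie, 0.0, out=movie)  # read noise never drives the signal negative

    mask = mask_from_rois(rois, (spec.height, spec.width))
    truth = {
        "centers": centers,
        "responsive": responsive,
        "dff": dff_truth,
        "onset": np.asarray(onset),
    }
    return ImageStack(movie, fps=trial.fps), mask, truth
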