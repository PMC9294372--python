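"""Online trial-by-trial identification of active neurons.

Two single-trial segmentation algorithms operate on a registered trial movie
plus its trial structure (baseline frames / response frames):

Algorithm #1 (cumulative dF/F + entropy threshold)
    Per-pixel dF/F against the baseline-period mean, summed over the response
    period and floored at zero, scaled by the per-pixel temporal SD of dF/F
    (which suppresses flat background drifts), then auto-thresholded with the
    three-order Renyi-entropy procedure and labelled with area and intensity
    filters.

Algorithm #2 (binary sensitivity index + exponential run amplification)
    Each pixel is binarised at 3 baseline SDs above its baseline mean; runs
    of consecutive supra-threshold frames are amplified by the recurrence
    ``L_t = alpha * chi_t * (L_{t-1} + beta)`` (so a run of n frames reaches
    ``(alpha^n - 1)/(alpha - 1)`` when ``beta = 1/alpha``); the temporal sum
    of ``L`` is smoothed with a cell-sized Gaussian window and thresholded at
    ``T = alpha*F + k`` where ``F`` is the indicator dynamic time in frames.
    Contiguous activity thus dominates scattered noise crossings.

Both algorithms are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .core import (
    DegenerateFrameError,
    ImageStack,
    LabelMask,
    ROI,
    TrialStructure,
    logger,
    mask_from_rois,
    sort_rois,
)

__all__ = [
    "Alg1Params",
    "Alg2Params",
    "PixelStats",
    "pixel_dff",
    "cumulative_dff_image",
    "renyi_threshold",
    "label_rois",
    "segment_trial_alg1",
    "baseline_stats",
    "binarize_stack",
    "amplify_runs",
    "sensitivity_image",
    "segment_trial_alg2",
]

_EPS = 2.220446049250313e-16


@dataclass
class Alg1Params:
    gaussian_sigma: float = 1.0  # px, smoothing of the thresholded binary image
    area_threshold: int = 16  # px^2, minimum ROI area
    intensity_threshold: float = 10.0  # cumulative-dF/F units, minimum ROI peak
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if self.area_threshold < 1:
            raise ValueError("area_threshold must be >= 1")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


@dataclass
class Alg2Params:
    alpha: float = 2.0  # run amplification base, > 1
    beta: float | None = None  # default alpha**-1
    indicator_frames: int = 5  # F: frames a real transient stays above threshold
    k: float = 0.0  # additive threshold offset
    smooth_sigma: float = 1.0  # px
    cell_window: int = 9  # px, odd Gaussian kernel truncation window
    threshold_mode: str = "linear"  # T = alpha*F + k; "geometric": alpha**F + k
    area_threshold: int = 16  # px^2
    stats_frames: str = "baseline"  # baseline statistics window: "baseline" | "all"

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.indicator_frames < 1:
            raise ValueError("indicator_frames must be >= 1")
        if self.cell_window < 3 or self.cell_window % 2 == 0:
            raise ValueError("cell_window must be odd and >= 3")
        if self.threshold_mode not in ("linear", "geometric"):
            raise ValueError("threshold_mode must be 'linear' or 'geometric'")
        if self.beta is None:
            self.beta = 1.0 / self.alpha

    @property
    def detection_threshold(self) -> float:
        if self.threshold_mode == "linear":
            return self.alpha * self.indicator_frames + self.k
        return self.alpha**self.indicator_frames + self.k


@dataclass
class PixelStats:
    """Per-pixel baseline mean and (population) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


def pixel_dff(stack: ImageStack, trial: TrialStructure) -> np.ndarray:
    """Per-pixel dF/F: ``(s - s_bar) / s_bar`` with s_bar the baseline mean.

    Pixels whose baseline mean is at or below a machine-safe epsilon
    (1e-6 of the dynamic range) get dF/F 0 and are counted in the log.
    """
    data = stack.data
    s_bar = data[trial.baseline_frames].mean(axis=0)
    eps = 1e-6 * max(float(data.max()), 1.0)
    bad = s_bar <= eps
    safe = np.where(bad, 1.0, s_bar)
    dff = (data - s_bar) / safe
    if bad.any():
        dff[:, bad] = 0.0
        logger.warning("pixel_dff: %d pixels with ~zero baseline set to dF/F = 0", bad.sum())
    return dff


def cumulative_dff_image(dff: np.ndarray, trial: TrialStructure) -> np.ndarray:
    """Cumulative response-period dF/F, floored at 0 and SD-scaled.

    The per-pixel temporal standard deviation of dF/F over the response
    period multiplies the floored sum, boosting transient pixels over
    equal-sum flat drifts.
    """
    resp = trial.response_frames
    if resp.size == 0:
        raise ValueError("response period is empty")
    s = dff[resp]
    v_tilde = np.maximum(0.0, s.sum(axis=0))
    return s.std(axis=0) * v_tilde


def _renyi_partial_entropies(p: np.ndarray, order: float) -> np.ndarray:
    """Background+foreground Renyi entropy for every candidate threshold bin.

    Entry ``t`` scores the split background = bins 0..t, foreground = t+1..;
    candidates with an empty side score -inf.
    """
    n = p.size
    p1 = np.cumsum(p)
    p2 = 1.0 - p1
    out = np.full(n, -np.inf)
    for t in range(n):
        # cumulative float sums can leave a ~1e-16 residue at the ends; both
        # sides of the split must carry real mass
        if p1[t] < 1e-12 or p2[t] < 1e-12:
            continue
        back = p[: t + 1] / p1[t]
        fore = p[t + 1 :] / p2[t]
        back = back[back > 0]
        fore = fore[fore > 0]
        if back.size == 0 or fore.size == 0:
            continue
        if order == 1.0:
            out[t] = -(back * np.log(back)).sum() - (fore * np.log(fore)).sum()
        else:
            out[t] = (np.log((back**order).sum()) + np.log((fore**order).sum())) / (
                1.0 - order
            )
    return out


def renyi_threshold_bin(hist: np.ndarray) -> int:
    """Three-order Renyi-entropy threshold bin of a histogram.

    Computes the optimal split for orders 0.5, 1 (Shannon limit) and 2,
    then combines the three sorted candidate bins with the published
    cumulative-probability beta weighting.
    """
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = hist / total
    stars = sorted(
        int(np.argmax(_renyi_partial_entropies(p, order))) for order in (0.5, 1.0, 2.0)
    )
    t1, t2, t3 = stars
    if abs(t1 - t2) <= 5:
        b1, b2, b3 = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b1, b2, b3 = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    p1 = np.cumsum(p)
    p2 = 1.0 - p1
    omega = p1[t3] - p1[t1]
    opt = (
        t1 * (p1[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (p2[t3] + 0.25 * omega * b3)
    )
    return int(opt)


def renyi_threshold(image: np.ndarray, bins: int = 256) -> float:
    """Renyi-entropy auto-threshold of an image, in original intensity units.

    The image is linearly rescaled to ``bins`` histogram bins; the selected
    bin's upper edge is mapped back to original units, so ``image > value``
    reproduces the binarisation.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateFrameError("no threshold: image is constant")
    hist, edges = np.histogram(image, bins=bins, range=(lo, hi))
    t_bin = renyi_threshold_bin(hist)
    return float(edges[t_bin + 1])


def label_rois(
    binary: np.ndarray,
    score_image: np.ndarray,
    sigma: float = 1.0,
    area_threshold: int = 16,
    intensity_threshold: float | None = None,
) -> LabelMask:
    """Turn a binary activity image into a filtered, sorted LabelMask.

    The binary image is Gaussian-smoothed (merging neighbouring positive
    pixels), re-binarised at 0.5, and 8-connected components are labelled.
    Components smaller than ``area_threshold`` pixels or whose peak value in
    ``score_image`` is below ``intensity_threshold`` are dropped.  ROIs are
    ordered by descending peak score.
    """
    binary = np.asarray(binary).astype(bool)
    if sigma > 0:
        smoothed = ndimage.gaussian_filter(binary.astype(np.float64), sigma)
        binary = smoothed >= 0.5
    labels = cc_label(binary, connectivity=2)
    rois: list[ROI] = []
    for lab in range(1, labels.max() + 1):
        pix = np.argwhere(labels == lab)
        if pix.shape[0] < area_threshold:
            continue
        peak = float(score_image[pix[:, 0], pix[:, 1]].max())
        if intensity_threshold is not None and peak < intensity_threshold:
            continue
        rois.append(ROI(id=0, pixels=pix, peak_score=peak))
    return mask_from_rois(sort_rois(rois), binary.shape)


def segment_trial_alg1(
    stack: ImageStack, trial: TrialStructure, params: Alg1Params | None = None
) -> LabelMask:
    """Algorithm #1: cumulative dF/F -> entropy threshold -> labelling."""
    params = params or Alg1Params()
    dff = pixel_dff(stack, trial)
    v = cumulative_dff_image(dff, trial)
    try:
        thr = renyi_threshold(v, bins=params.histogram_bins)
    except DegenerateFrameError:
        logger.info("segment_trial_alg1: flat cumulative image, no active pixels")
        return LabelMask.empty(v.shape)
    return label_rois(
        v > thr,
        score_image=v,
        sigma=params.gaussian_sigma,
        area_threshold=params.area_threshold,
        intensity_threshold=params.intensity_threshold,
    )


def baseline_stats(
    stack: ImageStack, trial: TrialStructure, frames: str = "baseline"
) -> PixelStats:
    """Per-pixel mean and population SD over the baseline (or all) frames."""
    if frames == "baseline":
        data = stack.data[trial.baseline_frames]
    elif frames == "all":
        data = stack.data
    else:
        raise ValueError("frames must be 'baseline' or 'all'")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames to estimate a baseline SD")
    return PixelStats(mean=data.mean(axis=0), sd=data.std(axis=0))


def binarize_stack(
    stack: ImageStack, trial: TrialStructure, stats_frames: str = "baseline"
) -> np.ndarray:
    """Binary sensitivity index: 1 where a pixel exceeds its baseline mean + 3 SD.

    Zero-SD pixels fall back to a tiny epsilon above the mean (counted in the
    log) so that a truly constant pixel never fires.
    """
    stats = baseline_stats(stack, trial, frames=stats_frames)
    sd = stats.sd
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("binarize_stack: %d zero-SD pixels use mean + eps", zero_sd.sum())
    eps = 1e-6 * max(float(stack.data.max()), 1.0)
    threshold = np.where(zero_sd, stats.mean + eps, stats.mean + 3.0 * sd)
    return (stack.data > threshold[np.newaxis]).astype(np.float64)


def amplify_runs(chi: np.ndarray, alpha: float = 2.0, beta: float | None = None) -> np.ndarray:
    """Exponential amplification of consecutive supra-threshold frames.

    ``L_1 = chi_1`` and ``L_t = alpha * chi_t * (L_{t-1} + beta)`` (the binary
    chi appears squared in the recurrence, which is the same thing).  With
    ``beta = 1/alpha`` a run of n ones reaches ``(alpha^n - 1)/(alpha - 1)``.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if beta is None:
        beta = 1.0 / alpha
    chi = np.asarray(chi, dtype=np.float64)
    out = np.empty_like(chi)
    out[0] = chi[0]
    for t in range(1, chi.shape[0]):
        out[t] = alpha * chi[t] * (out[t - 1] + beta)
    return out


def sensitivity_image(amplified: np.ndarray, params: Alg2Params | None = None) -> np.ndarray:
    """Temporal sum of the amplified index, smoothed with a cell-sized kernel.

    The Gaussian kernel (sigma ``smooth_sigma``) is truncated to a
    ``cell_window`` square and normalised to sum 1, so interior mass is
    conserved by the smoothing.
    """
    params = params or Alg2Params()
    total = np.asarray(amplified, dtype=np.float64).sum(axis=0)
    half = params.cell_window // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * params.smooth_sigma**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    return ndimage.convolve(total, kernel, mode="constant", cval=0.0)


def segment_trial_alg2(
    stack: ImageStack, trial: TrialStructure, params: Alg2Params | None = None
) -> LabelMask:
    """Algorithm #2: binarise -> amplify runs -> sensitivity image -> label."""
    params = params or Alg2Params()
    chi = binarize_stack(stack, trial, stats_frames=params.stats_frames)
    amplified = amplify_runs(chi, alpha=params.alpha, beta=params.beta)
    sens = sensitivity_image(amplified, params)
    binary = sens > params.detection_threshold
    score = pixel_dff(stack, trial).max(axis=0)  # peak pixel dF/F ranks the ROIs
    return label_rois(
        binary,
        score_image=score,
        sigma=0.0,
        area_threshold=params.area_threshold,
        intensity_threshold=None,
    )
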