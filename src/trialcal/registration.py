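"""Translation registration of fluorescence movies.

Each frame is aligned to a fixed template by minimising the windowed sum of
squared differences

    D(x, y) = 1 / ((h-|x|)(w-|y|)) * sum_{i,j} (t[i,j] - a[i+x, j+y])^2

over integer offsets ``(x, y)`` within a user-defined maximum shift ``Ms``.
For speed, only the central crop of each frame (margins of width ``Ms``
removed) is matched against the full template: the overlap area then becomes
a constant ``A' = (h-2Ms)(w-2Ms)``, the sum over the cropped frame of a'^2 is
offset-independent, and the only offset-dependent terms are a sliding-window
sum of t^2 (computed with an integral image) and the cross-correlation of the
crop with the template (computed with FFTs).  The argmin is exactly the
argmin of the brute-force cropped objective; scores within a tiny relative
tolerance are treated as tied and resolved by smallest ``|x|+|y|``, then
row-major ``(x, y)`` order, so the result is deterministic.

Shifts are integer-valued throughout: the model is rigid translation with no
sub-pixel refinement (a documented limitation), which also means registered
movies are produced by pure re-indexing with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import DegenerateFrameError, ImageStack, InvalidOffsetError, logger

__all__ = [
    "RegistrationParams",
    "standardize",
    "ssd_objective",
    "cropped_ssd_objective",
    "estimate_shift",
    "apply_shift",
    "register_stack",
]

# relative tolerance under which two objective scores count as an exact tie
_TIE_RTOL = 1e-9


@dataclass
class RegistrationParams:
    """Knobs of the translation search.

    ``max_shift`` (Ms) bounds the search window; the default, 1/5 of the
    smaller frame dimension, suits movies whose motion is small relative to
    the field of view.  ``template_index`` selects the reference frame
    (frame 0 by default).  With ``coarse_to_fine`` the shift is first
    estimated on a block-averaged image and then refined by exhaustive local
    search at full resolution in a ``+/-(downsample_factor+1)`` window.
    """

    max_shift: int | None = None
    template_index: int = 0
    coarse_to_fine: bool = False
    downsample_factor: int = 4
    fill_value: float = 0.0

    def resolve_max_shift(self, shape: tuple[int, int]) -> int:
        h, w = shape
        ms = self.max_shift if self.max_shift is not None else min(h, w) // 5
        if ms < 1 or ms >= min(h, w) / 2:
            raise ValueError(f"max_shift {ms} outside [1, min(h,w)/2) for frame {shape}")
        return int(ms)


def standardize(frame: np.ndarray) -> np.ndarray:
    """Mean-centre and scale a frame to unit (population) standard deviation."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 2:
        raise ValueError("frame must have at least 2 pixels")
    sd = frame.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateFrameError("degenerate frame: zero variance, cannot standardize")
    return (frame - frame.mean()) / sd


def ssd_objective(template: np.ndarray, frame: np.ndarray, x: int, y: int) -> float:
    """Reference overlap-normalised SSD between same-shape standardized images.

    This direct summation is the brute-force oracle for the FFT path; it is
    O(h*w) per offset and intended for tests and tiny inputs only.
    """
    template = np.asarray(template, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    if template.shape != frame.shape:
        raise ValueError("template and frame must share a shape")
    h, w = template.shape
    if abs(x) >= h or abs(y) >= w:
        raise InvalidOffsetError(f"offset ({x}, {y}) leaves no overlap for {h}x{w}")
    i0, i1 = max(0, -x), min(h, h - x)
    j0, j1 = max(0, -y), min(w, w - y)
    t_win = template[i0:i1, j0:j1]
    a_win = frame[i0 + x : i1 + x, j0 + y : j1 + y]
    area = (h - abs(x)) * (w - abs(y))
    return float(np.sum((t_win - a_win) ** 2) / area)


def cropped_ssd_objective(
    template: np.ndarray, frame: np.ndarray, x: int, y: int, max_shift: int
) -> float:
    """Brute-force value of the objective actually minimised by the FFT path.

    The frame is cropped by ``max_shift`` on every side and compared, at
    offset ``(x, y)``, against the matching window of the full template;
    the constant overlap area ``A' = (h-2Ms)(w-2Ms)`` normalises the score.
    """
    template = np.asarray(template, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    h, w = template.shape
    ms = int(max_shift)
    if abs(x) > ms or abs(y) > ms:
        raise InvalidOffsetError(f"offset ({x}, {y}) outside +/-{ms}")
    crop = frame[ms : h - ms, ms : w - ms]
    t_win = template[ms - x : h - ms - x, ms - y : w - ms - y]
    return float(np.sum((t_win - crop) ** 2) / crop.size)


def _window_sum_sq(template: np.ndarray, win_h: int, win_w: int) -> np.ndarray:
    """Sliding-window sum of template**2 for all valid window positions."""
    sq = template.astype(np.float64) ** 2
    # integral image with a zero border; exact, cheaper than an FFT
    ii = np.zeros((sq.shape[0] + 1, sq.shape[1] + 1))
    ii[1:, 1:] = sq.cumsum(axis=0).cumsum(axis=1)
    nh = sq.shape[0] - win_h + 1
    nw = sq.shape[1] - win_w + 1
    return (
        ii[win_h : win_h + nh, win_w : win_w + nw]
        - ii[:nh, win_w : win_w + nw]
        - ii[win_h : win_h + nh, :nw]
        + ii[:nh, :nw]
    )


def _score_table(template: np.ndarray, frame: np.ndarray, ms: int) -> np.ndarray:
    """(2Ms+1)^2 table of A'-normalised cropped SSD scores.

    Row p, column q correspond to offset x = Ms - p, y = Ms - q.
    """
    h, w = template.shape
    crop = frame[ms : h - ms, ms : w - ms]
    if crop.shape[0] < 4 or crop.shape[1] < 4:
        raise ValueError(f"Ms too large: central crop {crop.shape} smaller than 4x4")
    if crop.std() == 0:
        raise DegenerateFrameError("degenerate frame: constant central crop")
    # valid-mode cross-correlation of the template with the crop, via FFT
    cross = fftconvolve(template, crop[::-1, ::-1], mode="valid")
    win_sq = _window_sum_sq(template, crop.shape[0], crop.shape[1])
    scores = win_sq + np.sum(crop**2) - 2.0 * cross
    return scores / crop.size


def _argmin_with_ties(scores: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> tuple[int, int]:
    """Argmin with near-ties broken by smallest |x|+|y|, then (x, y) order."""
    m = scores.min()
    tol = _TIE_RTOL * max(1.0, float(np.abs(scores).max()))
    cand = np.flatnonzero(scores.ravel() <= m + tol)
    fx, fy = xs.ravel()[cand], ys.ravel()[cand]
    order = np.lexsort((fy, fx, np.abs(fx) + np.abs(fy)))
    return int(fx[order[0]]), int(fy[order[0]])


def estimate_shift(
    template: np.ndarray,
    frame: np.ndarray,
    params: RegistrationParams | None = None,
    *,
    _standardized: bool = False,
) -> tuple[int, int]:
    """Estimate the integer (dx, dy) translation of ``frame`` vs ``template``.

    Returns the offset minimising the cropped-frame SSD objective over
    ``(x, y) in [-Ms, Ms]^2``; positive ``dx`` means the frame content sits
    ``dx`` rows below the template.  Both images are standardized internally
    (idempotent), so raw intensity frames can be passed directly.
    """
    params = params or RegistrationParams()
    if not _standardized:
        template = standardize(template)
        frame = standardize(frame)
    if template.shape != frame.shape:
        raise ValueError("template and frame must share a shape")
    ms = params.resolve_max_shift(template.shape)

    if params.coarse_to_fine and params.downsample_factor > 1:
        return _estimate_coarse_to_fine(template, frame, ms, params.downsample_factor)

    scores = _score_table(template, frame, ms)
    offs = np.arange(ms, -ms - 1, -1)  # index p -> offset Ms - p
    xs, ys = np.meshgrid(offs, offs, indexing="ij")
    return _argmin_with_ties(scores, xs, ys)


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    h, w = (img.shape[0] // f) * f, (img.shape[1] // f) * f
    return img[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def _estimate_coarse_to_fine(
    template: np.ndarray, frame: np.ndarray, ms: int, factor: int
) -> tuple[int, int]:
    t_c = _block_mean(template, factor)
    a_c = _block_mean(frame, factor)
    ms_c = max(1, int(np.ceil(ms / factor)))
    ms_c = min(ms_c, (min(t_c.shape) - 4) // 2)  # keep the coarse crop >= 4x4
    scores_c = _score_table(standardize(t_c), standardize(a_c), ms_c)
    offs_c = np.arange(ms_c, -ms_c - 1, -1)
    xc, yc = np.meshgrid(offs_c, offs_c, indexing="ij")
    dx_c, dy_c = _argmin_with_ties(scores_c, xc, yc)

    # exhaustive local refinement at full resolution
    win = factor + 1
    xs = np.arange(max(-ms, factor * dx_c - win), min(ms, factor * dx_c + win) + 1)
    ys = np.arange(max(-ms, factor * dy_c - win), min(ms, factor * dy_c + win) + 1)
    local = np.empty((xs.size, ys.size))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            local[i, j] = cropped_ssd_objective(template, frame, int(x), int(y), ms)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return _argmin_with_ties(local, gx, gy)


def apply_shift(
    frame: np.ndarray, dx: int, dy: int, fill: float = 0.0
) -> np.ndarray:
    """Translate ``frame`` by ``(-dx, -dy)`` so it aligns to the template.

    Integer re-indexing only; pixels exposed at the borders are set to
    ``fill`` (default 0).
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if abs(dx) >= h or abs(dy) >= w:
        raise ValueError(f"shift ({dx}, {dy}) exceeds frame size {h}x{w}")
    out = np.full_like(frame, fill, dtype=frame.dtype)
    src_r = slice(max(0, dx), min(h, h + dx))
    dst_r = slice(max(0, -dx), min(h, h - dx))
    src_c = slice(max(0, dy), min(w, w + dy))
    dst_c = slice(max(0, -dy), min(w, w - dy))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def register_stack(
    stack: ImageStack,
    params: RegistrationParams | None = None,
    template: np.ndarray | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Register every frame of a movie against a fixed template.

    Parameters
    ----------
    stack:
        The movie to register.
    params:
        Search parameters; ``params.template_index`` picks the template frame
        when no explicit ``template`` image is given.
    template:
        Optional explicit template (e.g. a mean image) overriding the indexed
        frame.

    Returns
    -------
    registered, shifts:
        The registered movie (same shape, borders filled with
        ``params.fill_value``) and a ``T x 2`` integer array of per-frame
        ``(dx, dy)`` shifts.
    """
    params = params or RegistrationParams()
    if template is None:
        template = stack.frame(params.template_index)
    t_std = standardize(template)
    shifts = np.zeros((stack.n_frames, 2), dtype=np.int64)
    out = np.empty_like(stack.data)
    for k in range(stack.n_frames):
        try:
            f_std = standardize(stack.frame(k))
            dx, dy = estimate_shift(t_std, f_std, params, _standardized=True)
        except (DegenerateFrameError, ValueError) as exc:
            raise type(exc)(f"frame {k}: {exc}") from exc
        shifts[k] = (dx, dy)
        out[k] = apply_shift(stack.frame(k), dx, dy, fill=params.fill_value)
    logger.info(
        "registered %d frames (max |shift| = %d px)", stack.n_frames, np.abs(shifts).max()
    )
    return ImageStack(out, fps=stack.fps, pixel_size=stack.pixel_size), shifts
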