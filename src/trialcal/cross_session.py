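"""Cross-session alignment of repeated imaging of one field of view.

Sessions are represented by their time-averaged images.  The first (or a
chosen) session is the reference; every other session's average image is
aligned to it with a rigid (rotation + translation) or affine transform that
maximises image similarity (negative masked mean-squared error between
standardized images), searched over a multi-resolution pyramid with a fixed
rotation-initialisation grid, FFT translation initialisation and
derivative-free simplex refinement — fully deterministic.

A :class:`PlanarTransform` maps target-session ``(row, col)`` coordinates to
reference-session coordinates.  Label masks are warped with nearest-neighbour
sampling (labels are categorical); ROIs pushed outside the frame are cropped
or dropped.  Rotations beyond about 5 degrees push margin cells out of the
field of view and cannot be fully recovered — a physical limit of planar
re-imaging, not of the optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import ImageStack, LabelMask, ROI, logger
from .registration import RegistrationParams, estimate_shift, standardize
from .session_mask import SessionMask, merge_masks

__all__ = [
    "PlanarTransform",
    "time_average",
    "estimate_transform",
    "transform_mask",
    "unify_sessions",
]


@dataclass
class PlanarTransform:
    """A 2x3 planar map from target (row, col, 1) to reference coordinates."""

    matrix: np.ndarray  # 2x3
    kind: str = "affine"  # "rigid" | "affine"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("transform linear part is singular")
        if self.kind == "rigid":
            r = self.linear
            if not np.allclose(r @ r.T, np.eye(2), atol=1e-6) or np.linalg.det(r) < 0:
                raise ValueError("rigid transform must have a rotation linear part")

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def identity(cls, kind: str = "rigid") -> "PlanarTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]), kind=kind)

    @classmethod
    def rigid(
        cls,
        theta_deg: float,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "PlanarTransform":
        """Rotation by ``theta_deg`` about ``center`` plus a translation."""
        th = np.deg2rad(theta_deg)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=np.float64)
        t = c + np.asarray(translation, dtype=np.float64) - r @ c
        return cls(np.column_stack([r, t]), kind="rigid")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) target (row, col) points into reference coordinates."""
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return pts @ self.linear.T + self.translation

    def invert(self) -> "PlanarTransform":
        inv = np.linalg.inv(self.linear)
        return PlanarTransform(
            np.column_stack([inv, -inv @ self.translation]), kind=self.kind
        )

    def pull(
        self,
        image: np.ndarray,
        out_shape: tuple[int, int] | None = None,
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Pull-back resampling: ``out(q) = image(self(q))``.

        Aligning a target image into the reference frame is
        ``tf.invert().pull(target)``; building a synthetic target from a
        reference is ``tf.pull(reference)``.
        """
        return ndimage.affine_transform(
            np.asarray(image, dtype=np.float64),
            self.linear,
            offset=self.translation,
            output_shape=out_shape,
            order=order,
            mode="constant",
            cval=cval,
            prefilter=order > 1,
        )


def time_average(stack: ImageStack) -> np.ndarray:
    """Pixel-wise mean image of a session movie."""
    return stack.data.mean(axis=0)


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    h, w = (img.shape[0] // f) * f, (img.shape[1] // f) * f
    return img[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def _masked_mse(reference: np.ndarray, target: np.ndarray, tf: PlanarTransform) -> float:
    """MSE between the reference and the target aligned by ``tf``, over the
    pixels the warped target actually covers; heavily penalises transforms
    that throw most of the image out of the frame."""
    inv = tf.invert()
    aligned = inv.pull(target, out_shape=reference.shape)
    valid = inv.pull(np.ones_like(target), out_shape=reference.shape) > 0.999
    frac = valid.mean()
    if frac < 0.25:
        return 1e6 * (1.0 + (0.25 - frac))
    diff = reference[valid] - aligned[valid]
    return float(np.mean(diff**2))


def _rigid_from_params(p: np.ndarray, center: tuple[float, float]) -> PlanarTransform:
    return PlanarTransform.rigid(p[0], (p[1], p[2]), center)


def estimate_transform(
    reference: np.ndarray,
    target: np.ndarray,
    kind: str = "affine",
    max_init_angle: float = 6.0,
    angle_step: float = 2.0,
) -> PlanarTransform:
    """Estimate the planar transform aligning ``target`` to ``reference``.

    A rigid (theta, translation) solution is found first: rotation candidates
    on a fixed grid are each given an FFT translation initialisation, the
    best candidate is refined by Nelder-Mead over a 3-level image pyramid.
    ``kind="affine"`` then relaxes all six matrix entries starting from the
    rigid solution, and never returns a transform with worse similarity than
    its rigid initialisation.

    The transform maps target coordinates to reference coordinates; warp the
    target into the reference frame with ``tf.invert().pull(target)``.
    """
    if kind not in ("rigid", "affine"):
        raise ValueError("kind must be 'rigid' or 'affine'")
    reference = standardize(reference)
    target = standardize(target)
    if reference.shape != target.shape:
        raise ValueError("reference and target must share a shape")
    h, w = reference.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    levels = [f for f in (4, 2, 1) if min(h, w) // f >= 32]
    pyr = {
        f: (standardize(_block_mean(reference, f)), standardize(_block_mean(target, f)))
        for f in levels
    }

    def level_mse(p: np.ndarray, f: int, builder) -> float:
        ref_l, tgt_l = pyr[f]
        tf_full = builder(p)
        scaled = tf_full.matrix.copy()
        scaled[:, 2] /= f
        tf_l = PlanarTransform(scaled, kind="affine")
        return _masked_mse(ref_l, tgt_l, tf_l)

    # --- rigid stage: angle grid + FFT translation init at the coarsest level
    coarse = levels[0]
    ref_c, tgt_c = pyr[coarse]
    ms_c = max(2, min(ref_c.shape) // 4)
    best: tuple[float, np.ndarray] | None = None
    for theta in np.arange(-max_init_angle, max_init_angle + 1e-9, angle_step):
        rot = PlanarTransform.rigid(
            theta, (0.0, 0.0), (center[0] / coarse, center[1] / coarse)
        )
        warped = rot.invert().pull(tgt_c)
        try:
            dx, dy = estimate_shift(ref_c, warped, RegistrationParams(max_shift=ms_c))
        except Exception:  # degenerate warp at extreme angles: keep zero init
            dx, dy = 0, 0
        p0 = np.array([theta, -dx * coarse, -dy * coarse], dtype=np.float64)
        score = level_mse(p0, coarse, lambda p: _rigid_from_params(p, center))
        if best is None or score < best[0]:
            best = (score, p0)

    assert best is not None
    p_rigid = best[1]
    for f in levels:
        res = optimize.minimize(
            level_mse,
            p_rigid,
            args=(f, lambda p: _rigid_from_params(p, center)),
            method="Nelder-Mead",
            options={"xatol": 0.01 * f, "fatol": 1e-10, "maxiter": 400},
        )
        p_rigid = res.x
    rigid_tf = _rigid_from_params(p_rigid, center)
    rigid_mse = level_mse(p_rigid, 1, lambda p: _rigid_from_params(p, center))
    rigid_tf.diagnostics = {
        "mse": rigid_mse,
        "theta_deg": float(p_rigid[0]),
        "converged": bool(res.success),
    }
    if kind == "rigid":
        logger.info("rigid alignment: theta=%.3f deg, mse=%.4g", p_rigid[0], rigid_mse)
        return rigid_tf

    # --- affine stage: relax the full 2x3 matrix from the rigid solution
    def affine_from_params(p: np.ndarray) -> PlanarTransform:
        return PlanarTransform(p.reshape(2, 3), kind="affine")

    p_aff = rigid_tf.matrix.ravel().copy()
    for f in [lvl for lvl in levels if lvl <= 2] or [levels[-1]]:
        res = optimize.minimize(
            level_mse,
            p_aff,
            args=(f, affine_from_params),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 1200},
        )
        p_aff = res.x
    aff_mse = level_mse(p_aff, 1, affine_from_params)
    if aff_mse <= rigid_mse:
        tf = affine_from_params(p_aff)
        tf.diagnostics = {
            "mse": aff_mse,
            "rigid_mse": rigid_mse,
            "converged": bool(res.success),
        }
    else:  # affine refinement failed to improve; keep the rigid solution
        tf = PlanarTransform(rigid_tf.matrix, kind="affine")
        tf.diagnostics = {"mse": rigid_mse, "rigid_mse": rigid_mse, "converged": False}
        logger.warning("affine refinement did not improve on rigid; kept rigid matrix")
    logger.info("affine alignment: mse=%.4g (rigid %.4g)", tf.diagnostics["mse"], rigid_mse)
    return tf


def transform_mask(
    mask: LabelMask, tf: PlanarTransform, out_shape: tuple[int, int] | None = None
) -> LabelMask:
    """Map a label mask into the reference frame with nearest-neighbour warping.

    Labels are categorical: no interpolation ever mixes two ROIs.  ROIs
    falling entirely outside the output frame are dropped (logged); ROIs
    crossing the margin are cropped.  Original ROI ids and peak scores are
    preserved.
    """
    out_shape = out_shape or mask.shape
    inv = tf.invert()
    warped = inv.pull(mask.labels.astype(np.float64), out_shape=out_shape, order=0)
    warped = warped.astype(mask.labels.dtype)
    rois: list[ROI] = []
    dropped: list[int] = []
    for roi in mask.rois:
        pix = np.argwhere(warped == roi.id)
        if pix.size == 0:
            dropped.append(roi.id)
            continue
        rois.append(ROI(id=roi.id, pixels=pix, peak_score=roi.peak_score))
    if dropped:
        logger.info("transform_mask: ROIs %s fell outside the frame and were dropped", dropped)
    return LabelMask(labels=warped, rois=rois)


def unify_sessions(
    session_masks: list[LabelMask],
    transforms: list[PlanarTransform | None],
    reference_index: int = 0,
    overlap_fraction: float = 0.3,
) -> SessionMask:
    """Build the all-session capture-all mask in the reference frame.

    ``transforms[i]`` maps session ``i`` coordinates to the reference frame;
    the reference session's entry may be ``None`` (identity).  Every mask is
    warped into the reference frame and the results are merged with the
    capture-all union rule, so traces can afterwards be extracted per session
    through the unified ROI index.
    """
    if len(transforms) != len(session_masks):
        raise ValueError("need one transform entry per session")
    ref_shape = session_masks[reference_index].shape
    warped = []
    for i, (m, tf) in enumerate(zip(session_masks, transforms)):
        if i == reference_index or tf is None:
            warped.append(m)
        else:
            warped.append(transform_mask(m, tf, out_shape=ref_shape))
    return merge_masks(warped, overlap_fraction=overlap_fraction)
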