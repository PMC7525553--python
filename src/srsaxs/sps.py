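"""Subpixel-sampling super-resolution (SPS).

Frames recorded at detector translations of ``l/f`` are registered with a
translation-only Lucas–Kanade estimator and fused by robust shift-and-add
interlacing onto the ``l/f`` grid.  No deconvolution happens here: deblurring
is deliberately left to the multi-PSF deconvolution stage so the two steps
stay composable.

Coordinate conventions
----------------------
``estimate_shifts`` returns the *apparent content displacement* ``d_i`` of
each frame relative to the reference frame, in low-resolution pixels: a frame
whose sampling grid is translated by ``+o`` HR pixels shows its content
displaced by ``-o/f`` LR pixels.  ``fuse_sps`` takes absolute HR sampling
offsets ``h_i`` (floats); frame ``i``'s pixel ``r`` is placed at HR index
``f*r + round(h_i)``.  A detector pixel spans ``f`` HR cells, so the fused
canvas is displaced by ``(f-1)/2`` HR cells relative to the underlying
high-resolution scene (recorded in ``HighResImage.origin_shift``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from srsaxs.simulate import DetectorFrame

logger = logging.getLogger(__name__)


@dataclass
class ShiftEstimate:
    """Per-frame translation estimates relative to a reference frame.

    ``displacements[i] = (dx, dy)`` is the apparent content displacement of
    frame ``i`` in LR pixels (reference frame: exactly (0, 0)).
    """

    displacements: np.ndarray          # (n, 2) as (dx, dy), LR pixels
    residuals: np.ndarray              # final mean-squared registration error
    converged: np.ndarray              # per-frame convergence flag
    reference: int = 0


@dataclass
class HighResImage:
    """SPS-fused image on the ``l/f`` grid."""

    intensity: np.ndarray
    f: int
    fill_map: np.ndarray = field(default=None)  # True where >=1 sample landed
    offsets_used: list[tuple[int, int]] = field(default_factory=list)
    origin_shift: float = 0.0  # canvas index = scene HR index - origin_shift


# --------------------------------------------------------------------------
# Lucas–Kanade translation registration
# --------------------------------------------------------------------------

def _preprocess(img: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """log(1 + counts), lightly smoothed, zero-mean unit-std.

    The log compresses the ring dynamic range so the gradients near the
    beam center do not dominate the normal equations.
    """
    out = np.log1p(np.maximum(np.asarray(img, dtype=float), 0.0))
    if smooth_sigma > 0:
        out = ndimage.gaussian_filter(out, smooth_sigma)
    std = out.std()
    return (out - out.mean()) / (std if std > 0 else 1.0)


def _lk_single_level(
    ref: np.ndarray,
    mov: np.ndarray,
    d0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """Iterative translation-only Lucas–Kanade at one pyramid level.

    Solves for ``d`` (dy, dx) such that ``mov(x + d) ~= ref(x)``.
    """
    d = d0.astype(float).copy()
    margin = 3
    converged = False
    resid = np.inf
    for _ in range(max_iter):
        warped = ndimage.shift(mov, -d, order=3, mode="nearest")
        inner = (slice(margin, ref.shape[0] - margin), slice(margin, ref.shape[1] - margin))
        err = (ref - warped)[inner]
        gy, gx = np.gradient(warped)
        gy, gx = gy[inner], gx[inner]
        A = np.array([[np.sum(gy * gy), np.sum(gy * gx)],
                      [np.sum(gy * gx), np.sum(gx * gx)]])
        b = np.array([np.sum(gy * err), np.sum(gx * err)])
        try:
            step = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            break
        d += step
        resid = float(np.mean(err**2))
        if np.hypot(*step) < tol:
            converged = True
            break
    return d, resid, converged


def _downsample2(img: np.ndarray) -> np.ndarray:
    n, m = img.shape[0] // 2, img.shape[1] // 2
    return img[: 2 * n, : 2 * m].reshape(n, 2, m, 2).mean(axis=(1, 3))


def lucas_kanade_shift(
    ref: np.ndarray,
    mov: np.ndarray,
    pyramid_levels: int = 2,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> tuple[np.ndarray, float, bool]:
    """Estimate the translation ``(dy, dx)`` of ``mov`` relative to ``ref``.

    Returns the displacement such that the content of ``mov`` equals the
    content of ``ref`` moved by ``+d`` (i.e. ``mov == roll(ref, d)`` for
    integer shifts).  Coarse-to-fine over a small image pyramid.
    """
    ref_p = _preprocess(ref)
    mov_p = _preprocess(mov)
    pyramid = [(ref_p, mov_p)]
    for _ in range(pyramid_levels - 1):
        r, m = pyramid[-1]
        if min(r.shape) < 24:
            break
        pyramid.append((_downsample2(r), _downsample2(m)))
    d = np.zeros(2)
    resid, converged = np.inf, False
    for level in range(len(pyramid) - 1, -1, -1):
        r, m = pyramid[level]
        d, resid, converged = _lk_single_level(r, m, d, max_iter, tol)
        if level > 0:
            d *= 2.0
    return d, resid, converged


def estimate_shifts(
    frames: list[DetectorFrame] | list[np.ndarray],
    reference: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> ShiftEstimate:
    """Register every frame of one PSF group against a reference frame.

    Frames must share a PSF (registration across different blurs is out of
    scope).  A frame that fails to converge is flagged; the caller decides
    whether to substitute the nominal shift.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    imgs = [fr.counts if isinstance(fr, DetectorFrame) else np.asarray(fr) for fr in frames]
    psf_ids = {fr.psf_id for fr in frames if isinstance(fr, DetectorFrame)}
    if len(psf_ids) > 1:
        raise ValueError(f"frames mix PSFs {sorted(psf_ids)}; register within one PSF group")
    n = len(imgs)
    disp = np.zeros((n, 2))
    resid = np.zeros(n)
    conv = np.ones(n, dtype=bool)
    ref = imgs[reference]
    for i, img in enumerate(imgs):
        if i == reference:
            continue
        d, r, ok = lucas_kanade_shift(ref, img, max_iter=max_iter, tol=tol)
        disp[i] = d[::-1]  # store as (dx, dy)
        resid[i] = r
        conv[i] = ok
        if not ok:
            logger.warning("frame %d registration did not converge (residual %.3g)", i, r)
    return ShiftEstimate(displacements=disp, residuals=resid, converged=conv, reference=reference)


# --------------------------------------------------------------------------
# interlacing fusion
# --------------------------------------------------------------------------

def fuse_sps(
    frames: list[DetectorFrame] | list[np.ndarray],
    offsets_hr: np.ndarray,
    f: int,
    normalize: bool = True,
) -> HighResImage:
    """Fuse shifted LR frames onto the ``l/f`` grid by robust shift-and-add.

    Parameters
    ----------
    frames : LR frames (or plain arrays), all the same shape.
    offsets_hr : (n, 2) array of absolute sampling offsets ``(oy, ox)`` in HR
        pixels (floats; rounded to the nearest lattice position for
        placement — estimation keeps full precision, placement is lattice).
    f : enhancement factor.
    normalize : scale the output so its total equals ``f**2`` times the mean
        per-frame flux, making each HR cell an estimate of the ``f x f``
        box-sum signal at that position.

    Coincident samples are combined by median (robust to hot pixels and
    cosmic counts); HR cells receiving no sample are filled from the nearest
    filled cell and flagged in ``fill_map``.
    """
    imgs = [np.asarray(fr.counts if isinstance(fr, DetectorFrame) else fr, dtype=float)
            for fr in frames]
    offsets_hr = np.atleast_2d(np.asarray(offsets_hr, dtype=float))
    if len(imgs) != len(offsets_hr):
        raise ValueError("one offset per frame required")
    M, Mx = imgs[0].shape
    H, Hx = f * M + f - 1, f * Mx + f - 1
    if f == 1:
        out = imgs[0] if len(imgs) == 1 else np.median(np.stack(imgs), axis=0)
        return HighResImage(out.copy(), f=1, fill_map=np.ones_like(out, bool),
                            offsets_used=[(0, 0)], origin_shift=0.0)

    slots = np.rint(offsets_hr).astype(int)
    # group frames landing on the same lattice residue, aligning whole-pixel parts
    groups: dict[tuple[int, int], list[np.ndarray]] = {}
    for img, (sy, sx) in zip(imgs, slots):
        ry, rx = sy % f, sx % f
        ky, kx = sy // f, sx // f
        aligned = np.full((M, Mx), np.nan)
        src = img[max(0, -ky) : M - max(0, ky), max(0, -kx) : Mx - max(0, kx)]
        aligned[max(0, ky) : M - max(0, -ky), max(0, kx) : Mx - max(0, -kx)] = src
        groups.setdefault((ry, rx), []).append(aligned)

    if len(groups) == 1 and f > 1 and len(imgs) > 1:
        warnings.warn(
            "all frames share one sub-pixel position; fusion is degenerate "
            "(returns an upsampled single position)",
            stacklevel=2,
        )

    canvas = np.full((H, Hx), np.nan)
    for (ry, rx), stack in groups.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(np.stack(stack), axis=0)
        canvas[ry::f, rx::f][:M, :Mx] = med

    fill_map = np.isfinite(canvas)
    if not fill_map.all():
        _, (iy, ix) = ndimage.distance_transform_edt(~fill_map, return_indices=True)
        canvas = canvas[iy, ix]

    if normalize:
        mean_flux = float(np.mean([img.sum() for img in imgs]))
        total = canvas.sum()
        if total > 0:
            canvas *= (f**2) * mean_flux / total

    return HighResImage(
        intensity=canvas,
        f=f,
        fill_map=fill_map,
        offsets_used=sorted(groups.keys()),
        origin_shift=(f - 1) / 2.0,
    )
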