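"""Forward model for synthetic SAXS acquisitions.

Generates isotropic ground-truth scattering patterns (Lorentzian rings over a
1/q background with a central beamstop), rasterises slit-aperture x
Gaussian-source point-spread functions, blurs the pattern, and samples
Poisson-noise detector frames at sub-pixel detector translations.

Conventions
-----------
* The *high-resolution* (HR) grid has pitch ``l/f`` where ``l`` is the
  physical pixel size and ``f`` the resolution enhancement factor; pixel
  centers sit on integer coordinates and the beam center is given as
  ``(row, col)`` floats.
* A detector translation is an integer offset ``(dx, dy)`` in HR pixels,
  ``0 <= dx, dy < f``.  Sampling crops the HR image at that offset and
  box-sums ``f x f`` cells (counts are additive photon tallies), then draws
  ``Poisson(t * cell_sum)`` per detector pixel.
* All convolutions use symmetric (reflective) padding cropped to shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from srsaxs._convolve import reflect_convolve


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthPattern:
    """Ring list + background + beamstop defining the ground-truth intensity.

    Parameters
    ----------
    rings : list of (radius, width, amplitude)
        Lorentzian rings; radius and half-width-at-half-maximum ``gamma`` in
        HR pixels, amplitude in counts per unit exposure time.  The
        Lorentzian is used unnormalised, with peak value ``A`` at the ring
        radius, so quoted amplitudes are directly the ring peak heights.
    background_coeff : float
        Scale of the spurious background, ``I_bkg = background_coeff / rho``
        (reciprocal to the distance from the beam center).
    beamstop_radius : float
        Radius (HR pixels) of the opaque beamstop masking the central
        singularity; intensity is 0 inside.
    center : (row, col)
        Beam center in HR pixel coordinates.
    grid_shape : (rows, cols)
        HR grid shape.
    """

    rings: tuple[tuple[float, float, float], ...]
    background_coeff: float = 0.0
    beamstop_radius: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    grid_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")
        for radius, width, amp in self.rings:
            if radius <= 0 or width <= 0 or amp <= 0:
                raise ValueError("ring radius, width and amplitude must be > 0")
        if self.beamstop_radius < 0:
            raise ValueError("beamstop_radius must be >= 0")
        if self.background_coeff < 0:
            raise ValueError("background_coeff must be >= 0")


@dataclass(frozen=True)
class PSFModel:
    """Parametric beam profile: slit aperture convolved with a Gaussian source.

    The 1D profile along each axis is a width-``w`` rectangle convolved with a
    sigma-``s`` Gaussian, i.e. a difference of two error functions; the 2D
    kernel is the separable product.  ``w_x``, ``w_y`` and ``source_sigma``
    are physical lengths; ``pixel_pitch`` converts them to render-grid pixels
    (with the default pitch of 1 they read directly as HR pixels).

    ``flux_scale`` is the kernel sum relative to the reference (smallest) PSF
    of a set: wider slits pass proportionally more photons, so the total
    intensity of a frame is tied to the slit area.
    """

    w_x: float
    w_y: float
    source_sigma: float = 0.0
    pixel_pitch: float = 1.0
    flux_scale: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.w_x < 0 or self.w_y < 0 or self.source_sigma < 0:
            raise ValueError("PSF widths must be >= 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.flux_scale <= 0:
            raise ValueError("flux_scale must be > 0")

    @property
    def psf_id(self) -> str:
        return self.name or f"psf_w{self.w_x:g}x{self.w_y:g}_s{self.source_sigma:g}"


@dataclass
class DetectorFrame:
    """One recorded/simulated detector image (integer photon counts)."""

    counts: np.ndarray
    exposure: float
    nominal_shift: tuple[int, int]  # (dx, dy) in HR (l/f) pixels
    psf_id: str
    f: int
    pixel_size: float = 172.0  # physical pixel pitch l, micrometres
    mask: np.ndarray | None = None
    aperture: str = "box"  # "box": integrate f x f HR cells; "point": sample cell center

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        dx, dy = self.nominal_shift
        if not (0 <= dx < self.f and 0 <= dy < self.f):
            raise ValueError("nominal shift outside [0, f)")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        elif self.mask.shape != self.counts.shape:
            raise ValueError("mask shape mismatch")


@dataclass
class FrameSet:
    """A measurement set: frames plus the distinct PSFs they reference."""

    frames: list[DetectorFrame]
    psf_models: list[PSFModel]
    protocol: str = "plain"
    f: int = 1
    hr_center: tuple[float, float] | None = None  # beam center on the HR grid

    def __post_init__(self) -> None:
        ids = {fr.psf_id for fr in self.frames}
        known = {p.psf_id for p in self.psf_models}
        if not ids <= known:
            raise ValueError(f"frames reference unknown PSF ids: {ids - known}")
        shapes = {fr.counts.shape for fr in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")

    @property
    def m(self) -> int:
        """Number of distinct PSFs referenced by the frames."""
        return len({fr.psf_id for fr in self.frames})

    def by_psf(self) -> dict[str, list[DetectorFrame]]:
        groups: dict[str, list[DetectorFrame]] = {}
        for fr in self.frames:
            groups.setdefault(fr.psf_id, []).append(fr)
        return groups


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def radial_distance(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Euclidean distance of every pixel center from ``center``."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    return np.hypot(rows - center[0], cols - center[1])


def render_ground_truth(pattern: GroundTruthPattern) -> np.ndarray:
    """Render the noiseless HR ground-truth intensity I_GT.

    ``I(rho) = sum_rings A * gamma^2 / ((rho - R)^2 + gamma^2) + c / rho`` for
    ``rho > beamstop_radius``; 0 behind the beamstop (which also removes the
    1/rho singularity at the center).
    """
    rho = radial_distance(pattern.grid_shape, pattern.center)
    r_max = rho.max()
    image = np.zeros(pattern.grid_shape, dtype=float)
    for radius, width, amp in pattern.rings:
        if radius > r_max:
            warnings.warn(
                f"ring radius {radius} lies beyond the grid (max rho {r_max:.1f}); "
                "ring truncated",
                stacklevel=2,
            )
        image += amp * width**2 / ((rho - radius) ** 2 + width**2)
    if pattern.background_coeff > 0:
        with np.errstate(divide="ignore"):
            image += np.where(rho > 0, pattern.background_coeff / np.maximum(rho, 1e-12), 0.0)
    image[rho <= pattern.beamstop_radius] = 0.0
    if not np.all(np.isfinite(image)):
        raise FloatingPointError("non-finite intensity in rendered pattern")
    return image


def _erf_profile(u: np.ndarray, w: float, s: float) -> np.ndarray:
    """Rectangle(width w) x Gaussian(sigma s) profile sampled at ``u``.

    Continuous unit-height-rectangle convolution; mass ``w`` for s, w > 0.
    Degenerate limits: w=0 -> unit-mass Gaussian; s=0 -> sampled indicator.
    """
    if w == 0 and s == 0:
        out = np.zeros_like(u)
        out[np.abs(u) < 0.5] = 1.0  # delta on the sampling grid
        return out
    if s == 0:
        out = np.zeros_like(u)
        out[np.abs(u) < w / 2] = 1.0
        out[np.isclose(np.abs(u), w / 2)] = 0.5
        return out
    if w == 0:
        return np.exp(-(u**2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
    a = (u + w / 2) / (np.sqrt(2) * s)
    b = (u - w / 2) / (np.sqrt(2) * s)
    return 0.5 * (special.erf(a) - special.erf(b))


def render_psf(model: PSFModel, support: int) -> np.ndarray:
    """Rasterise a PSF model on a ``support x support`` grid (odd support).

    The kernel is the separable product of two erf-difference profiles,
    scaled so its sum equals ``flux_scale``.  Raises if the support truncates
    more than 1e-4 of the analytic mass along either axis.
    """
    if support < 3 or support % 2 == 0:
        raise ValueError("support must be odd and >= 3")
    half = support // 2
    u = np.arange(-half, half + 1, dtype=float) * model.pixel_pitch
    u_big = np.arange(-4 * half - 2, 4 * half + 3, dtype=float) * model.pixel_pitch
    profiles = []
    for w in (model.w_y, model.w_x):
        k = _erf_profile(u, w, model.source_sigma)
        k_big = _erf_profile(u_big, w, model.source_sigma)
        if k_big.sum() <= 0:
            raise ValueError("degenerate PSF profile with zero mass")
        captured = k.sum() / k_big.sum()
        if captured < 1 - 1e-4:
            raise ValueError(
                f"support {support} too small for slit width {w} and source sigma "
                f"{model.source_sigma}: captures only {captured:.6f} of the mass"
            )
        profiles.append(k)
    kernel = np.outer(profiles[0], profiles[1])
    kernel *= model.flux_scale / kernel.sum()
    return kernel


def psf_support_for(model: PSFModel, minimum: int = 3) -> int:
    """Smallest odd support comfortably holding the PSF mass."""
    w = max(model.w_x, model.w_y)
    half = int(np.ceil((w / 2 + 5 * model.source_sigma) / model.pixel_pitch)) + 1
    support = 2 * half + 1
    return max(support, minimum)


def default_psf_set(
    smallest: float,
    source_sigma: float = 1.0,
    pixel_pitch: float = 1.0,
    step: float = 1.0,
) -> list[PSFModel]:
    """Six engineered PSFs from three slit sizes ``s, s+1, s+2`` (HR pixels).

    The set is the three squares plus the three rectangular combinations of
    those sizes.  ``flux_scale`` is proportional to the slit area ``w_x*w_y``
    and normalised so the smallest PSF has flux 1 — wider slits pass more
    photons and hence yield higher-SNR (but more blurred) frames.
    """
    sizes = [smallest, smallest + step, smallest + 2 * step]
    combos = [
        (sizes[0], sizes[0]),
        (sizes[1], sizes[1]),
        (sizes[2], sizes[2]),
        (sizes[0], sizes[1]),
        (sizes[0], sizes[2]),
        (sizes[1], sizes[2]),
    ]
    area0 = combos[0][0] * combos[0][1]
    return [
        PSFModel(
            w_x=wx,
            w_y=wy,
            source_sigma=source_sigma,
            pixel_pitch=pixel_pitch,
            flux_scale=(wx * wy) / area0,
            name=f"psf{i}_w{wx:g}x{wy:g}",
        )
        for i, (wx, wy) in enumerate(combos)
    ]


# --------------------------------------------------------------------------
# blurring and sampling
# --------------------------------------------------------------------------

def blur(image: np.ndarray, psf_kernel: np.ndarray) -> np.ndarray:
    """Smear an HR intensity image with a PSF kernel (reflective boundary).

    Linear in the image; flux gain equals the kernel sum.
    """
    return reflect_convolve(image, psf_kernel)


def lr_shape(hr_shape: tuple[int, int], f: int) -> tuple[int, int]:
    """Detector (low-resolution) shape: HR cells grouped in ``f x f`` blocks,
    uniform across all ``f`` crop offsets."""
    return ((hr_shape[0] - f + 1) // f, (hr_shape[1] - f + 1) // f)


def sample_frame(
    image_hr: np.ndarray,
    shift: tuple[int, int],
    f: int,
    t: float,
    rng: np.random.Generator | int,
    psf_id: str = "psf",
    pixel_size: float = 172.0,
    aperture: str = "box",
) -> DetectorFrame:
    """Draw one Poisson detector frame at sub-pixel offset ``shift``.

    Each detector pixel covers an ``f x f`` block of HR cells starting at
    offset ``(dy, dx)``.  With the physical ``"box"`` aperture (default) its
    count is ``Poisson(t * block_sum)`` — photon tallies are additive over
    the pixel area.  The idealised ``"point"`` aperture instead samples the
    block-center HR cell, ``Poisson(t * f^2 * center_value)``: a decimating
    detector with the same flux but no in-pixel integration, which is the
    regime in which pure sub-pixel sampling can resolve structure finer
    than the pixel pitch (in-pixel integration nulls exactly the
    period-``f`` frequencies a complete shift grid would otherwise restore).
    """
    dx, dy = shift
    if not (0 <= dx < f and 0 <= dy < f):
        raise ValueError(f"shift {shift} outside [0, {f})")
    if t < 0:
        raise ValueError("exposure must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_lr, m_lr = lr_shape(image_hr.shape, f)
    crop = image_hr[dy : dy + n_lr * f, dx : dx + m_lr * f]
    if aperture == "box":
        cells = crop.reshape(n_lr, f, m_lr, f).sum(axis=(1, 3))
    elif aperture == "point":
        c = (f - 1) // 2
        cells = f**2 * crop[c::f, c::f][:n_lr, :m_lr]
    else:
        raise ValueError(f"unknown aperture {aperture!r}")
    lam = t * np.maximum(cells, 0.0)  # FFT blur can leave ~1e-15 negatives
    counts = rng.poisson(lam)
    return DetectorFrame(
        counts=counts,
        exposure=t,
        nominal_shift=(dx, dy),
        psf_id=psf_id,
        f=f,
        pixel_size=pixel_size,
        aperture=aperture,
    )


def grid_shifts(f: int) -> list[tuple[int, int]]:
    """The full ``f x f`` sub-pixel translation grid, row-major."""
    return [(dx, dy) for dy in range(f) for dx in range(f)]


def simulate_acquisition(
    pattern: GroundTruthPattern,
    psf_models: list[PSFModel],
    f: int,
    shifts: list[tuple[int, int]],
    t_per_frame: float,
    seed: int | np.random.SeedSequence,
    protocol: str | None = None,
    aperture: str = "box",
) -> FrameSet:
    """Simulate a full acquisition: render once, blur per PSF, sample per shift.

    One frame is produced for every (PSF, shift) pair, each with its own
    child seed derived from ``seed``, so a fixed root seed reproduces the
    whole set.
    """
    if not psf_models:
        raise ValueError("need at least one PSF model")
    if not shifts:
        raise ValueError("need at least one shift")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(psf_models) * len(shifts))
    gt = render_ground_truth(pattern)
    frames: list[DetectorFrame] = []
    k = 0
    for model in psf_models:
        kernel = render_psf(model, psf_support_for(model))
        blurred = blur(gt, kernel)
        for shift in shifts:
            frames.append(
                sample_frame(
                    blurred,
                    shift,
                    f,
                    t_per_frame,
                    np.random.default_rng(children[k]),
                    psf_id=model.psf_id,
                    aperture=aperture,
                )
            )
            k += 1
    if protocol is None:
        if len(psf_models) == 1 and len(shifts) == 1:
            protocol = "plain"
        elif len(psf_models) == 1:
            protocol = "SPS"
        elif len(shifts) == 1:
            protocol = "CMD"
        else:
            protocol = "SrSAXS"
    return FrameSet(
        frames=frames,
        psf_models=list(psf_models),
        protocol=protocol,
        f=f,
        hr_center=pattern.center,
    )


def two_ring_pattern(
    r1: float = 30.0,
    r2: float = 34.0,
    width: float = 0.9,
    amp1: float = 1.0,
    amp2: float = 0.6,
    f: int = 3,
    lr_grid: int = 85,
    background_coeff: float = 1.0,
    beamstop_radius: float = 3.0,
) -> GroundTruthPattern:
    """Two close Lorentzian circles — the standard doublet fixture.

    Radii, widths, the background scale and the beamstop radius are given in
    *detector* pixels (``l``), the natural unit of the apparatus; the pattern
    is rendered on the high-resolution ``l/f`` grid, so internally they are
    multiplied by ``f``.  The HR grid has ``f * lr_grid + f - 1`` pixels per
    side (``lr_grid`` detector pixels at every sub-pixel crop offset).
    """
    grid = f * lr_grid + f - 1
    c = (grid - 1) / 2.0
    return GroundTruthPattern(
        rings=((f * r1, f * width, amp1), (f * r2, f * width, amp2)),
        background_coeff=f * background_coeff,
        beamstop_radius=f * beamstop_radius,
        center=(c, c),
        grid_shape=(grid, grid),
    )
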