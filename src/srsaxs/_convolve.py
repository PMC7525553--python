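"""Shared convolution helpers.

All forward-model and solver convolutions in this package use symmetric
(reflective) padding cropped back to the original shape: wrap-around would
alias scattering rings across detector edges, while reflection keeps flux
nearly conserved for interior-dominated patterns.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def reflect_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2D convolution with reflective boundary, output same shape as ``image``.

    The kernel may have any sum (its sum is the flux gain of the operation).
    """
    if not (np.all(np.isfinite(image)) and np.all(np.isfinite(kernel))):
        raise ValueError("non-finite values in convolution inputs")
    ky, kx = kernel.shape
    if ky > image.shape[0] or kx > image.shape[1]:
        raise ValueError("kernel larger than image")
    py, px = ky // 2, kx // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="symmetric")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[py : py + image.shape[0], px : px + image.shape[1]]


def circular_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular (periodic) convolution via FFT; kernel centered then wrapped."""
    K = psf_otf(kernel, image.shape)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * K))


def psf_otf(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed a centered PSF kernel into ``shape`` and return its transfer function.

    Equivalent to MATLAB's ``psf2otf``: the kernel center lands on index (0, 0)
    so that the OTF phase corresponds to a zero-shift blur.
    """
    ky, kx = kernel.shape
    if ky > shape[0] or kx > shape[1]:
        raise ValueError("kernel larger than target shape")
    big = np.zeros(shape, dtype=float)
    big[:ky, :kx] = kernel
    big = np.roll(big, (-(ky // 2), -(kx // 2)), axis=(0, 1))
    return np.fft.fft2(big)


def box_kernel(f: int) -> np.ndarray:
    """f x f box-sum kernel modelling integration over a detector pixel."""
    return np.ones((f, f), dtype=float)
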