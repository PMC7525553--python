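# srsaxs — angular super-resolution retrieval for SAXS

Laboratory small-angle X-ray scattering (SAXS) instruments trade angular
resolution against photon flux: the detector pixels are large compared to
the scattering features of interest, and a tightly collimated beam (a
narrow point-spread function) costs exposure time. `srsaxs` implements a
two-stage computational retrieval that recovers resolution lost to both
effects, for people who reduce and analyse 2D SAXS detector images:

1. **Subpixel sampling (SPS).** The detector is translated on an
   `f x f` grid of sub-pixel steps of size `l/f` (`l` the pixel pitch).
   The shifted frames are registered with a translation-only Lucas–Kanade
   estimator and fused by robust (median) shift-and-add interlacing onto
   the `l/f` grid, synthesising an effectively `f`-times-finer pixel.
2. **Constrained multi-deconvolution (CMD).** The sample is exposed
   through `m` engineered beam shapes (scatterless-slit apertures
   convolved with the Gaussian source), giving observations
   `Y_i = P_i * X`. The de-smeared image is the minimiser of the weighted
   ridge-regularised least-squares objective

   ```
   X̂ = argmin_X  Σ_i ||Y_i − P_i * X||_F² / (2σ_i²) + ν ||X||_F²
   ```

   solved per spatial frequency (a multi-image Wiener filter) on a
   reflect-padded domain, with optional non-negativity projection. The
   weights σ_i balance sharp-but-noisy small-slit frames against
   bright-but-smeared large-slit ones.

Run one after the other — fusion first, deconvolution second — the two
stages give the combined *SrSAXS* retrieval. Resolution is scored on the
1D azimuthally integrated profile `I(q)` with the peak-separation
criterion

```
δ = (I_p − I_v) / Δq
```

where `I_p` is the intensity of the lower of two nearby peaks, `I_v` the
valley between them and `Δq` their separation; `δ = 0` means the doublet
is unresolved.

The package also ships the full synthetic forward model used to validate
the method (Lorentzian scattering rings over a 1/q background, beamstop,
PSF blur, Poisson counting statistics, sub-pixel detector translations),
the instrument geometry / azimuthal integration utilities, two reference
baselines (Richardson–Lucy deconvolution and a full Farsiu-style
super-resolution with bilateral-total-variation deconvolution), and an
equal-exposure-budget comparison of the four acquisition protocols
(plain / SPS / CMD / SrSAXS).

## Worked example

Two Lorentzian rings at radii 30 and 34 detector pixels (widths 0.9,
amplitudes 1 and 0.6) are unresolvable in a plain exposure through the
smallest available slit, but resolved by the combined retrieval at the
same total exposure:

```python
from srsaxs import (
    two_ring_pattern, default_psf_set, grid_shifts, simulate_acquisition,
    srsaxs_retrieve, plain_retrieve, CMDConfig,
)

pattern = two_ring_pattern()                    # rings at 30 and 34 detector px
psfs = default_psf_set(8.0, source_sigma=1.0)   # six slit x Gaussian beams

# 54 frames: 9 sub-pixel positions (f=3) for each of 6 PSFs, 10 time units each
frames = simulate_acquisition(pattern, psfs, f=3, shifts=grid_shifts(3),
                              t_per_frame=10.0, seed=1)
ret = srsaxs_retrieve(frames, CMDConfig(nu=0.01, weight_mode="balanced",
                                        nonnegativity=True))
res = ret.delta(window=(25, 40))
print(f"SrSAXS:  delta = {res.delta:.3f}  "
      f"(peaks at {res.peak_positions[0]:.1f} and {res.peak_positions[1]:.1f} px, "
      f"valley at {res.valley_position:.1f} px)")

# equal-budget reference: one 540-unit exposure through the smallest PSF
plain = simulate_acquisition(pattern, psfs[:1], f=3, shifts=[(0, 0)],
                             t_per_frame=540.0, seed=1, protocol="plain")
print(f"plain:   delta = {plain_retrieve(plain).delta(window=(25, 40)).delta:.3f}")
```

prints

```
SrSAXS:  delta = 0.174  (peaks at 30.0 and 34.0 px, valley at 32.0 px)
plain:   delta = 0.016
```

i.e. the combined retrieval separates the doublet (peaks recovered at the
true radii, with a clear valley) while the equal-time plain measurement
leaves it essentially merged. The delta axis is in detector-pixel units;
intensities are normalised to ground-truth units (counts per unit
exposure through a unit-flux PSF), so values are comparable across
protocols.

A command-line interface mirrors the library
(`srsaxs simulate|register|fuse|cmd|retrieve|integrate|delta|baseline|compare`);
every verb takes `--help`.

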