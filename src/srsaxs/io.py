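"""Reading and writing framesets, PSFs, masks and radial profiles.

Frames are stored one TIFF per frame (32-bit integer counts) with a JSON
sidecar carrying acquisition metadata; masks are 8-bit TIFF (0 invalid /
1 valid); PSF kernels are 32-bit float TIFF.  Radial profiles are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from srsaxs.geometry import RadialProfile
from srsaxs.simulate import DetectorFrame, FrameSet, PSFModel


def write_frameset(frameset: FrameSet, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "protocol": frameset.protocol,
        "f": frameset.f,
        "hr_center": list(frameset.hr_center) if frameset.hr_center else None,
        "psf_models": [
            {
                "psf_id": p.psf_id,
                "w_x": p.w_x,
                "w_y": p.w_y,
                "source_sigma": p.source_sigma,
                "pixel_pitch": p.pixel_pitch,
                "flux_scale": p.flux_scale,
            }
            for p in frameset.psf_models
        ],
        "n_frames": len(frameset.frames),
    }
    (directory / "frameset.json").write_text(json.dumps(meta, indent=2))
    for i, fr in enumerate(frameset.frames):
        stem = directory / f"frame_{i:04d}"
        tifffile.imwrite(stem.with_suffix(".tif"), fr.counts.astype(np.int32))
        tifffile.imwrite(
            directory / f"mask_{i:04d}.tif", fr.mask.astype(np.uint8)
        )
        sidecar = {
            "t": fr.exposure,
            "dx": fr.nominal_shift[0],
            "dy": fr.nominal_shift[1],
            "f": fr.f,
            "psf_id": fr.psf_id,
            "pixel_size_um": fr.pixel_size,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_frameset(directory: str | Path) -> FrameSet:
    directory = Path(directory)
    meta = json.loads((directory / "frameset.json").read_text())
    models = [
        PSFModel(
            w_x=p["w_x"],
            w_y=p["w_y"],
            source_sigma=p["source_sigma"],
            pixel_pitch=p["pixel_pitch"],
            flux_scale=p["flux_scale"],
            name=p["psf_id"],
        )
        for p in meta["psf_models"]
    ]
    frames = []
    for i in range(meta["n_frames"]):
        stem = directory / f"frame_{i:04d}"
        counts = tifffile.imread(stem.with_suffix(".tif"))
        mask_path = directory / f"mask_{i:04d}.tif"
        mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
        side = json.loads(stem.with_suffix(".json").read_text())
        frames.append(
            DetectorFrame(
                counts=counts,
                exposure=side["t"],
                nominal_shift=(side["dx"], side["dy"]),
                psf_id=side["psf_id"],
                f=side["f"],
                pixel_size=side.get("pixel_size_um", 172.0),
                mask=mask,
            )
        )
    return FrameSet(
        frames=frames,
        psf_models=models,
        protocol=meta["protocol"],
        f=meta["f"],
        hr_center=tuple(meta["hr_center"]) if meta.get("hr_center") else None,
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_profile(path: str | Path, profile: RadialProfile, q: np.ndarray | None = None) -> None:
    df = pd.DataFrame(
        {
            "radius_px": profile.bins,
            "intensity": profile.intensity,
            "spread": profile.spread,
            "n_pixels": profile.n_pixels,
        }
    )
    if q is not None:
        df.insert(0, "q", q)
    df.to_csv(Path(path), index=False)


def read_profile(path: str | Path) -> RadialProfile:
    df = pd.read_csv(Path(path))
    bins = df["radius_px"].to_numpy()
    width = float(np.median(np.diff(bins))) if len(bins) > 1 else 1.0
    return RadialProfile(
        bins=bins,
        intensity=df["intensity"].to_numpy(),
        spread=df["spread"].to_numpy(),
        n_pixels=df["n_pixels"].to_numpy(),
        bin_width=width,
    )
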