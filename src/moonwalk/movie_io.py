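"""Lossless export/import of stimulus movies as frame stacks + JSON sidecar.

A movie directory contains:

* ``frames.tif`` — the luminance stack (float32 TIFF, lossless) or a
  ``frame_0000.png`` series (16-bit PNG; decoded values are snapped back
  to the sidecar's recorded luminance levels, so the round trip is exact
  for the discrete-level stimuli produced here);
* ``masks.tif`` — center and surround masks as a 2-page uint8 stack;
* ``hidden_texture.tif`` — the ground-truth translating center texture;
* ``sidecar.json`` — the full generating spec plus format metadata.

On import the center mask is regenerated from the sidecar spec; a mismatch
with the stored mask (e.g. a tampered seed) triggers a validation warning.
An AVI demo export is available when an ffmpeg-backed imageio plugin is
installed; it is lossy and never used for round trips.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .stimgen import FrameSequence, StimulusSpec, make_center_mask

__all__ = ["export_movie", "import_movie", "export_avi", "SidecarMismatchWarning"]

_SIDECAR = "sidecar.json"


class SidecarMismatchWarning(UserWarning):
    """The sidecar metadata is inconsistent with the stored frames."""


def export_movie(sequence: FrameSequence, path: str | Path, format: str = "tiff") -> Path:
    """Write a movie directory; returns its path."""
    if format not in ("tiff", "png"):
        raise ValueError("format must be 'tiff' or 'png'")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    levels = sorted(float(v) for v in np.unique(sequence.frames))
    if format == "tiff":
        tifffile.imwrite(out / "frames.tif", sequence.frames.astype(np.float32))
    else:
        import imageio.v3 as iio

        codes = np.round(sequence.frames.astype(np.float64) * 65535).astype(np.uint16)
        for t in range(sequence.n_frames):
            iio.imwrite(out / f"frame_{t:04d}.png", codes[t])
    masks = np.stack(
        [sequence.center_mask, sequence.surround_mask]
    ).astype(np.uint8)
    tifffile.imwrite(out / "masks.tif", masks)
    tifffile.imwrite(out / "hidden_texture.tif", sequence.hidden_texture.astype(np.uint8))
    sidecar = {
        "spec": sequence.spec.to_dict(),
        "format": format,
        "n_frames": sequence.n_frames,
        "depth_model": sequence.depth_model,
        "n_switch_rate": sequence.n_switch_rate,
        "texture_origin": list(sequence.texture_origin),
        "luminance_levels": levels,
    }
    (out / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return out


def import_movie(path: str | Path) -> FrameSequence:
    """Read a movie directory back into a :class:`FrameSequence`."""
    src = Path(path)
    sidecar_path = src / _SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        spec = StimulusSpec.from_dict(sidecar["spec"])
        fmt = sidecar["format"]
        n_frames = int(sidecar["n_frames"])
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    if fmt == "tiff":
        frames = tifffile.imread(src / "frames.tif").astype(np.float32)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        import imageio.v3 as iio

        levels = np.asarray(sidecar["luminance_levels"], dtype=np.float64)
        stack = []
        for t in range(n_frames):
            codes = iio.imread(src / f"frame_{t:04d}.png").astype(np.float64) / 65535.0
            nearest = np.abs(codes[..., None] - levels[None, None, :]).argmin(axis=-1)
            stack.append(levels[nearest])
        frames = np.asarray(stack, dtype=np.float32)
    masks = tifffile.imread(src / "masks.tif").astype(bool)
    center_mask, surround_mask = masks[0], masks[1]
    hidden = tifffile.imread(src / "hidden_texture.tif").astype(bool)

    if frames.shape[0] != n_frames:
        warnings.warn(
            f"sidecar records {n_frames} frames but stack holds {frames.shape[0]}",
            SidecarMismatchWarning,
        )
    regenerated = make_center_mask(
        spec.frame_size_px,
        spec.stimulus_diameter_deg,
        spec.pixels_per_degree,
        spec.center_outline_seed,
        spec.outline_perturbation,
    )
    if not np.array_equal(regenerated, center_mask):
        warnings.warn(
            "center mask regenerated from the sidecar spec does not match the "
            "stored mask; the sidecar seed may not be the generator's",
            SidecarMismatchWarning,
        )
    return FrameSequence(
        frames=frames,
        center_mask=center_mask,
        surround_mask=surround_mask,
        spec=spec,
        hidden_texture=hidden,
        texture_origin=tuple(sidecar.get("texture_origin", (0, 0))),
        depth_model=sidecar.get("depth_model", "F"),
        n_switch_rate=float(sidecar.get("n_switch_rate", 0.05)),
    )


def export_avi(sequence: FrameSequence, path: str | Path, fps: float | None = None) -> Path:
    """Lossy AVI demo export (requires an ffmpeg-backed imageio plugin)."""
    import imageio.v2 as iio

    fps = fps if fps is not None else sequence.spec.frame_rate_hz
    frames8 = np.clip(sequence.frames * 255.0, 0, 255).astype(np.uint8)
    try:
        iio.mimwrite(str(path), list(frames8), fps=fps)
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise RuntimeError(
            "AVI export needs an ffmpeg-capable imageio backend "
            "(e.g. the imageio-ffmpeg plugin)"
        ) from exc
    return Path(path)
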