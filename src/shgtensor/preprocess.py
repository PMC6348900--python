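"""Stack preprocessing: frame averaging, depth referencing, stroma partition.

Acquisition protocol emulated here: at each depth location three sequential
frames are recorded and averaged into the final SHG image; the 0 um depth is
re-referenced to the first plane inside the stroma where SHG signal appears;
the stroma is split into anterior / mid / posterior thirds of its thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import FrameSet, ImageStack, SHGImage

__all__ = [
    "StromaPartition",
    "average_frames",
    "total_intensity",
    "locate_stroma_origin",
    "partition_thirds",
    "radiant_exposure",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class StromaPartition:
    """Anterior/mid/posterior thirds of a stroma of given thickness (um).

    Intervals are half-open [lo, hi) except the last, which is closed at the
    full thickness, so every depth maps to exactly one third.
    """

    thickness_um: float
    anterior: tuple
    mid: tuple
    posterior: tuple

    def location_of(self, depth_um: float) -> str:
        if not 0 <= depth_um <= self.thickness_um:
            raise ValueError(f"depth {depth_um} outside [0, {self.thickness_um}]")
        if depth_um < self.anterior[1]:
            return "anterior"
        if depth_um < self.mid[1]:
            return "mid"
        return "posterior"


def average_frames(frames: FrameSet) -> SHGImage:
    """Pixel-wise arithmetic mean of repeated frames (SNR optimization)."""
    mean = np.mean(np.stack(frames.frames, axis=0), axis=0)
    return SHGImage(mean, frames.pixel_size_um, frames.depth_um,
                    dict(frames.label))


def total_intensity(image: SHGImage) -> float:
    """Sum of all pixel intensities of one plane."""
    return float(np.sum(image.intensity))


def locate_stroma_origin(stack: ImageStack, signal_threshold: float = 0.1) -> int:
    """Find the first plane where SHG signal appears and re-reference depths.

    A plane counts as "signal" when its total intensity exceeds
    ``signal_threshold`` times the maximum per-plane total intensity of the
    stack.  The stack's ``origin_index`` is set and every plane's depth is
    shifted so that plane has depth 0.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    totals = np.array([total_intensity(p) for p in stack.planes])
    cutoff = signal_threshold * totals.max()
    above = np.nonzero(totals > cutoff) if signal_threshold > 0 else \
        np.nonzero(totals > 0)
    idx = above[0]
    if idx.size == 0:
        raise ValueError("no plane exceeds the signal threshold")
    origin = int(idx[0])
    origin_depth = stack.planes[origin].depth_um
    for p in stack.planes:
        p.depth_um = p.depth_um - origin_depth
    stack.origin_index = origin
    return origin


def partition_thirds(thickness_um: float) -> StromaPartition:
    """Split [0, thickness] into three equal-depth thirds.

    E.g. a 240 um stroma has its anterior/mid boundary at 80 um and mid/
    posterior boundary at 160 um.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    lo, hi = thickness_um / 3.0, 2.0 * thickness_um / 3.0
    return StromaPartition(thickness_um, (0.0, lo), (lo, hi),
                           (hi, thickness_um))


def radiant_exposure(irradiance_mw_per_cm2: float, duration_min: float) -> float:
    """UVA dose in J/cm^2 from irradiance (mW/cm^2) and duration (minutes).

    The standard epi-off cross-linking protocol (3 mW/cm^2 for 30 min)
    delivers 5.4 J/cm^2.
    """
    if irradiance_mw_per_cm2 <= 0 or duration_min <= 0:
        raise ValueError("irradiance and duration must be positive")
    return irradiance_mw_per_cm2 * 1e-3 * duration_min * 60.0


# ---------------------------------------------------------------------------
# TIFF + sidecar JSON I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, tiff_path, meta: dict | None = None) -> None:
    """Write a stack as a multi-page float32 TIFF plus a sidecar JSON.

    One page per depth plane, anterior first.  The sidecar (same path with
    ``.json``) records pixel size, plane spacing, depths and any metadata.
    """
    tiff_path = Path(tiff_path)
    data = np.stack([p.intensity.astype(np.float32) for p in stack.planes])
    tifffile.imwrite(tiff_path, data, photometric="minisblack")
    side = {
        "pixel_size_um": stack.planes[0].pixel_size_um,
        "plane_spacing_um": stack.plane_spacing_um,
        "depths_um": [p.depth_um for p in stack.planes],
        "origin_index": stack.origin_index,
        "labels": [p.label for p in stack.planes],
    }
    if meta:
        side.update(meta)
    tiff_path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_stack(tiff_path, pixel_size_um: float | None = None,
               plane_spacing_um: float | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    8/16-bit integer data are promoted to float.  A sidecar JSON written by
    :func:`write_stack` supplies pixel size and plane spacing; explicit
    arguments override it.
    """
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path).astype(float)
    if data.ndim == 2:
        data = data[None]
    side = {}
    sidecar = tiff_path.with_suffix(".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
    px = pixel_size_um or side.get("pixel_size_um", 1.0)
    spacing = plane_spacing_um or side.get("plane_spacing_um", 20.0)
    depths = side.get("depths_um") or [k * spacing for k in range(len(data))]
    labels = side.get("labels") or [{"plane": k} for k in range(len(data))]
    planes = [SHGImage(frame, px, d, lab)
              for frame, d, lab in zip(data, depths, labels)]
    return ImageStack(planes, spacing, side.get("origin_index", 0))
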