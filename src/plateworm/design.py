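"""Back-of-envelope design arithmetic for a multi-camera plate imager.

These helpers capture the sizing constraints of an array of machine-vision
cameras recording a full 96-well plate at worm-pose resolution: the pixel
budget needed to cover the plate, the raw data rate the cameras produce,
and the spatial resolution implied by the optics.
"""

from __future__ import annotations

#: Long/short side of a standard microplate footprint that must be covered,
#: in pixels, at the target resolution of 75 px/mm with a 3:2 aspect ratio.
PLATE_PIXEL_BUDGET = (8100, 5400)


def pixel_budget_megapixels(width_px: int = 8100, height_px: int = 5400) -> float:
    """Total sensor megapixels required to cover the imaged area."""
    if width_px <= 0 or height_px <= 0:
        raise ValueError("pixel dimensions must be positive")
    return width_px * height_px / 1e6


def raw_data_rate_tb_per_hour(
    megapixels: float = 12.0,
    fps: float = 25.0,
    n_cameras: int = 6,
    bytes_per_pixel: int = 1,
) -> float:
    """Raw (uncompressed) footage produced per hour, in TB (10^12 bytes).

    8-bit grayscale frames: one byte per pixel.
    """
    if megapixels <= 0 or fps <= 0 or n_cameras <= 0:
        raise ValueError("rates and counts must be positive")
    return megapixels * 1e6 * bytes_per_pixel * fps * n_cameras * 3600 / 1e12


def resolution_px_per_mm(um_per_px: float = 12.4) -> float:
    """Spatial resolution in px/mm for a given sampling in µm per pixel."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    return 1000.0 / um_per_px


def meets_resolution_target(um_per_px: float = 12.4, target_px_per_mm: float = 75.0) -> bool:
    """Whether the optics meet the minimum resolution needed for pose estimation."""
    return resolution_px_per_mm(um_per_px) >= target_px_per_mm


def simultaneous_wells(n_units: int = 5, wells_per_plate: int = 96) -> int:
    """Number of wells recorded in parallel across identical imaging units."""
    if n_units < 1 or wells_per_plate < 1:
        raise ValueError("counts must be >= 1")
    return n_units * wells_per_plate
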