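"""Display mapping: bipolar PA colormap, negative-clipped MIP, and the
purple/cyan dual-modality fusion.

The PA colormap is symmetric about zero — strong negative pressure renders
black, zero mid-gray, strong positive white — so both lobes of a bipolar
point feature read as "strong signal".  Fusion renders US in purple
(1, 0, 1) and PA in cyan (0, 1, 1) with additive blending, so pixels where
both modalities peak together turn white: the signature of the marker clip
in a co-registered PA/US frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidParameterError
from .reconstruct import Image, ImageGrid, Volume

__all__ = [
    "DisplaySpec",
    "RGBImage",
    "bipolar_colormap",
    "mip_render",
    "fuse_images",
    "save_png",
    "save_tiff",
]

PURPLE = np.array([1.0, 0.0, 1.0])
CYAN = np.array([0.0, 1.0, 1.0])


@dataclass(frozen=True)
class DisplaySpec:
    """Normalization knobs for display: PA amplitudes are scaled by the
    given percentile of |values| (robust to hot pixels); US B-mode dynamic
    range and gain are in dB."""

    pa_percentile_clip: float = 99.9
    us_dynamic_range: float = 40.0
    gain: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.pa_percentile_clip <= 100:
            raise InvalidParameterError("pa_percentile_clip must lie in (0, 100]")
        if self.us_dynamic_range <= 0:
            raise InvalidParameterError("us_dynamic_range must be positive")


@dataclass
class RGBImage:
    """Fused/display image with channels in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise InvalidParameterError("RGB values must have shape [nz, nx, 3]")
        if self.values.min() < 0 or self.values.max() > 1:
            raise InvalidParameterError("RGB channels must lie in [0, 1]")


def _pa_scale(values: np.ndarray, percentile: float) -> float:
    return float(np.percentile(np.abs(values), percentile))


def bipolar_colormap(image: Image, spec: DisplaySpec | None = None) -> RGBImage:
    """Symmetric gray mapping of a bipolar PA image.

    Most negative -> black, zero -> mid-gray, most positive -> white, with
    the scale set by the spec's percentile of |values|.  An all-zero image
    renders uniform mid-gray.
    """
    if image.modality != "PA":
        raise InvalidParameterError("bipolar_colormap expects a PA image")
    if spec is None:
        spec = DisplaySpec()
    scale = _pa_scale(image.values, spec.pa_percentile_clip)
    if scale == 0:
        gray = np.full(image.values.shape, 0.5)
    else:
        gray = (np.clip(image.values / scale, -1.0, 1.0) + 1.0) / 2.0
    return RGBImage(np.repeat(gray[:, :, None], 3, axis=2))


def mip_render(volume: Volume, axis: str = "y") -> Image:
    """Maximum intensity projection with negative values set to zero.

    ``axis`` names the projection direction: "y" (elevational, the usual
    top view onto the imaging plane), "x" (lateral), or "z" (depth).  The
    output image's rows/columns follow the two remaining axes in (y, z, x)
    storage order.
    """
    axis_map = {"y": 0, "z": 1, "x": 2}
    if axis not in axis_map:
        raise InvalidParameterError("axis must be one of 'x', 'y', 'z'")
    clipped = np.maximum(volume.values, 0.0)
    proj = clipped.max(axis=axis_map[axis])
    if axis == "y":
        grid = volume.grid
    else:
        ys = volume.y_positions
        dy = float(ys[1] - ys[0]) if len(ys) > 1 else volume.grid.pixel_spacing
        if axis == "x":  # rows y, cols z
            grid = ImageGrid(
                x_min=volume.grid.z_min,
                x_max=volume.grid.z_min + (proj.shape[1] - 1) * volume.grid.pixel_spacing + 1e-12,
                z_min=float(ys[0]),
                z_max=float(ys[0]) + (proj.shape[0] - 1) * dy + 1e-12,
                pixel_spacing=volume.grid.pixel_spacing,
            )
        else:  # axis == "z": rows y, cols x
            grid = ImageGrid(
                x_min=volume.grid.x_min,
                x_max=volume.grid.x_min + (proj.shape[1] - 1) * volume.grid.pixel_spacing + 1e-12,
                z_min=float(ys[0]),
                z_max=float(ys[0]) + (proj.shape[0] - 1) * dy + 1e-12,
                pixel_spacing=volume.grid.pixel_spacing,
            )
        if grid.shape != proj.shape:  # non-uniform y spacing: fall back to index grid
            grid = ImageGrid(
                x_min=0.0,
                x_max=(proj.shape[1] - 1) * volume.grid.pixel_spacing + 1e-12,
                z_min=0.0,
                z_max=(proj.shape[0] - 1) * volume.grid.pixel_spacing + 1e-12,
                pixel_spacing=volume.grid.pixel_spacing,
            )
    return Image(proj, grid, "PA")


def fuse_images(pa: Image, us: Image, spec: DisplaySpec | None = None) -> RGBImage:
    """Purple/cyan additive fusion of co-registered PA and US images.

    US-only pixels render purple, PA-only pixels cyan, and joint maxima
    white.  ``us`` must be a B-mode image (already in [0, 1]); ``pa`` is
    normalized by |values| at the spec's percentile.
    """
    if spec is None:
        spec = DisplaySpec()
    if pa.modality != "PA":
        raise InvalidParameterError("fuse_images expects a PA image first")
    if us.modality != "US_bmode":
        raise InvalidParameterError("fuse_images expects a US_bmode image second")
    if pa.grid != us.grid:
        raise InvalidParameterError("PA and US images must share one grid")
    scale = _pa_scale(pa.values, spec.pa_percentile_clip)
    p = np.clip(np.abs(pa.values) / scale, 0.0, 1.0) if scale > 0 else np.zeros(pa.grid.shape)
    u_max = us.values.max()
    u = us.values / u_max if u_max > 0 else np.zeros(us.grid.shape)
    rgb = np.clip(u[:, :, None] * PURPLE + p[:, :, None] * CYAN, 0.0, 1.0)
    return RGBImage(rgb)


def _draw_scale_bar(
    rgb8: np.ndarray, pixel_spacing: float, bar_length: float
) -> np.ndarray:
    """Burn a white scale bar into the bottom-left corner."""
    nz, nx = rgb8.shape[:2]
    bar_px = int(round(bar_length / pixel_spacing))
    if bar_px < 2 or bar_px > nx - 8:
        return rgb8
    height = max(2, nz // 100)
    margin = max(4, nz // 50)
    rgb8[nz - margin - height : nz - margin, margin : margin + bar_px] = 255
    return rgb8


def save_png(
    image,
    path,
    spec: DisplaySpec | None = None,
    scale_bar: float | None = 10e-3,
) -> None:
    """Write an 8-bit PNG; bipolar PA images go through the symmetric gray
    map, B-mode through a plain gray map, RGBImage as-is.  A scale bar
    (default 10 mm) is drawn when the pixel spacing is known."""
    pixel_spacing = None
    if isinstance(image, RGBImage):
        rgb = image.values
    elif isinstance(image, Image):
        pixel_spacing = image.grid.pixel_spacing
        if image.modality == "PA":
            rgb = bipolar_colormap(image, spec).values
        else:
            gray = np.clip(image.values, 0.0, 1.0)
            if image.modality == "US_rf":
                mag = np.abs(image.values)
                gray = mag / mag.max() if mag.max() > 0 else mag
            rgb = np.repeat(gray[:, :, None], 3, axis=2)
    else:
        raise InvalidParameterError("save_png expects an Image or RGBImage")
    rgb8 = (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)
    if scale_bar is not None and pixel_spacing is not None:
        rgb8 = _draw_scale_bar(rgb8, pixel_spacing, scale_bar)
    iio.imwrite(str(path), rgb8)


def save_tiff(obj, path) -> None:
    """Write a 16-bit TIFF: single page for an Image, multi-page (one page
    per elevational slice) for a Volume.  Values are min-max scaled."""
    if isinstance(obj, Image):
        data = obj.values
    elif isinstance(obj, Volume):
        data = obj.values
    else:
        raise InvalidParameterError("save_tiff expects an Image or Volume")
    lo, hi = float(data.min()), float(data.max())
    scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    tifffile.imwrite(str(path), (scaled * 65535).round().astype(np.uint16))
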