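"""Delay-and-sum reconstruction with angular apodization.

Each pixel p is formed independently (the same per-pixel decomposition the
real-time system parallelizes):

    I(p) = sum_i w_i(p) s_i(tau_i(p)) / sum_i w_i(p)

with the one-way delay tau_i = |p - r_i| / c for PA and the round-trip
2 |p - r_i| / c for monostatic US RF data.  Channel samples are linearly
interpolated; delays outside the record contribute nothing.  The angular
weight is w_i = cos^q(theta_i) for theta_i <= max_angle (else 0), theta_i
being the angle between element i's normal and the direction to the pixel;
normalizing by sum w flattens aperture falloff so depth trends reflect
physics (1/r spreading, optical fluence) rather than element coverage.

PA images stay bipolar: no envelope detection and no non-negativity
constraint, because bipolar point features are what make the marker clip
recognizable.  B-mode display for US applies per-column envelope detection
and log compression separately (:func:`us_bmode`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.ndimage import label as _cc_label
from scipy.signal import hilbert

from .arrays import ArrayGeometry, Pose, apply_pose, concatenate_geometries
from .errors import CoverageWarning, InvalidParameterError, NoPeakError
from .forward_model import ChannelData

__all__ = [
    "ImageGrid",
    "Image",
    "WeightingSpec",
    "Volume",
    "Peak",
    "das_reconstruct",
    "us_bmode",
    "rf_envelope",
    "multi_view_reconstruct",
    "reconstruct_volume",
    "locate_peak",
    "feature_extent",
    "lateral_fwhm",
]


@dataclass(frozen=True)
class ImageGrid:
    """Metric pixel grid; pixel (0, 0) center at (x_min, z_min), row index
    along depth z, column index along lateral x."""

    x_min: float
    x_max: float
    z_min: float
    z_max: float
    pixel_spacing: float

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise InvalidParameterError("pixel_spacing must be positive")
        if not (self.x_max > self.x_min and self.z_max > self.z_min):
            raise InvalidParameterError("grid extents must be non-degenerate")

    @property
    def x(self) -> np.ndarray:
        n = int(math.floor((self.x_max - self.x_min) / self.pixel_spacing + 1e-9)) + 1
        return self.x_min + np.arange(n) * self.pixel_spacing

    @property
    def z(self) -> np.ndarray:
        n = int(math.floor((self.z_max - self.z_min) / self.pixel_spacing + 1e-9)) + 1
        return self.z_min + np.arange(n) * self.pixel_spacing

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.z), len(self.x)


@dataclass
class Image:
    """Reconstructed amplitude on a grid.  PA images are bipolar; US_rf is
    the bipolar beamformed RF image; US_bmode is the nonnegative display."""

    values: np.ndarray
    grid: ImageGrid
    modality: str  # "PA" | "US_rf" | "US_bmode"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.modality not in ("PA", "US_rf", "US_bmode"):
            raise InvalidParameterError(f"unknown image modality {self.modality!r}")


@dataclass(frozen=True)
class WeightingSpec:
    """Angular apodization: w = cos^q(theta), cut off beyond max_angle."""

    angular_exponent: float = 1.0
    max_angle: float = math.radians(60.0)

    def __post_init__(self) -> None:
        if self.angular_exponent < 0:
            raise InvalidParameterError("angular_exponent must be >= 0")
        if not 0 < self.max_angle <= math.pi / 2:
            raise InvalidParameterError("max_angle must lie in (0, pi/2]")


@dataclass
class Volume:
    """Stack of reconstructed slices: values[y, z, x] with the shared
    in-plane grid and the elevational slice positions."""

    values: np.ndarray
    grid: ImageGrid
    y_positions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.y_positions = np.asarray(self.y_positions, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("volume values must be 3D [y, z, x]")
        if self.values.shape[0] != len(self.y_positions):
            raise InvalidParameterError("one y position per slice required")


class Peak(NamedTuple):
    x: float
    z: float
    amplitude: float


def das_reconstruct(
    channels: ChannelData,
    grid: ImageGrid,
    speed_of_sound: float = 1500.0,
    weights: WeightingSpec | None = None,
) -> Image:
    """Delay-and-sum beamforming of one channel-data record onto a grid.

    The adjustable reconstruction sound speed is deliberately independent of
    the simulation's medium speed (it is an operator control on the real
    system).  Pixels with zero total weight, or reachable only at delays
    outside the record, are set to 0 (the latter with a coverage warning).
    """
    if speed_of_sound <= 0:
        raise InvalidParameterError("speed_of_sound must be positive")
    if weights is None:
        weights = WeightingSpec()
    delay_factor = 2.0 if channels.modality == "US" else 1.0
    fs, t0, n_t = channels.sampling_rate, channels.t0, channels.n_samples
    cos_cut = math.cos(weights.max_angle)
    q = weights.angular_exponent

    X, Z = np.meshgrid(grid.x, grid.z)
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    possible = np.zeros(grid.shape)  # sum of angular weights ignoring the record window
    positions = channels.geometry.element_positions
    normals = channels.geometry.element_normals
    for i in range(channels.n_elements):
        dx = X - positions[i, 0]
        dz = Z - positions[i, 1]
        r = np.hypot(dx, dz)
        r_safe = np.where(r > 0, r, 1.0)
        cos_theta = (normals[i, 0] * dx + normals[i, 1] * dz) / r_safe
        cos_theta = np.where(r > 0, cos_theta, 1.0)
        w = np.where(cos_theta >= cos_cut, cos_theta, 0.0)
        if q != 1.0:
            w = np.where(w > 0, w**q, 0.0) if q != 0 else (w > 0).astype(float)
        s = (delay_factor * r / speed_of_sound - t0) * fs
        i0 = np.floor(s).astype(int)
        frac = s - i0
        valid = (i0 >= 0) & (i0 + 1 < n_t)
        i0c = np.clip(i0, 0, n_t - 2)
        row = channels.samples[i]
        vals = row[i0c] * (1.0 - frac) + row[i0c + 1] * frac
        w_eff = np.where(valid, w, 0.0)
        num += w_eff * np.where(valid, vals, 0.0)
        den += w_eff
        possible += w
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if np.any((den == 0) & (possible > 0)):
        warnings.warn(
            "some pixels are outside the recorded time window for every element",
            CoverageWarning,
        )
    modality = "PA" if channels.modality == "PA" else "US_rf"
    return Image(out, grid, modality)


def rf_envelope(image: Image) -> np.ndarray:
    """Linear envelope of a beamformed RF image: magnitude of the analytic
    signal along depth, column by column.  Unnormalized, so envelopes of
    different images are directly comparable."""
    if image.modality not in ("US_rf", "PA"):
        raise InvalidParameterError("rf_envelope expects a bipolar RF image")
    return np.abs(hilbert(image.values, axis=0))


def us_bmode(image: Image, dynamic_range: float = 40.0, gain: float = 0.0) -> Image:
    """B-mode display image: envelope, normalize to max, log-compress.

    Output values lie in [0, 1]; 1 is the image maximum (plus gain), 0 is
    ``dynamic_range`` dB below it.  ``gain`` (dB) is added before clipping.
    """
    if image.modality != "US_rf":
        raise InvalidParameterError("us_bmode expects an US_rf image")
    if dynamic_range <= 0:
        raise InvalidParameterError("dynamic_range must be positive")
    env = rf_envelope(image)
    peak = env.max()
    if peak == 0:
        return Image(np.zeros(image.grid.shape), image.grid, "US_bmode")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    out = np.clip((db + gain) / dynamic_range + 1.0, 0.0, 1.0)
    return Image(out, image.grid, "US_bmode")


def multi_view_reconstruct(
    views: list[tuple[ChannelData, Pose]],
    grid: ImageGrid,
    speed_of_sound: float = 1500.0,
    weights: WeightingSpec | None = None,
) -> Image:
    """Multi-angle joint reconstruction: coherent DAS over all posed views.

    Each view's geometry is rigidly posed into the common frame and the
    union of elements is beamformed as one aperture — equivalent to
    :func:`das_reconstruct` on the concatenated geometry.  Views must share
    sampling parameters and modality.
    """
    if not views:
        raise InvalidParameterError("need at least one view")
    first_cd = views[0][0]
    for cd, _ in views[1:]:
        if (
            cd.sampling_rate != first_cd.sampling_rate
            or cd.t0 != first_cd.t0
            or cd.n_samples != first_cd.n_samples
            or cd.modality != first_cd.modality
        ):
            raise InvalidParameterError("all views must share sampling and modality")
    posed = [apply_pose(cd.geometry, pose) for cd, pose in views]
    combined_geom = concatenate_geometries(posed)
    combined = ChannelData(
        samples=np.vstack([cd.samples for cd, _ in views]),
        sampling_rate=first_cd.sampling_rate,
        t0=first_cd.t0,
        modality=first_cd.modality,
        geometry=combined_geom,
    )
    return das_reconstruct(combined, grid, speed_of_sound, weights)


def reconstruct_volume(
    per_slice_views: list[tuple[float, list[tuple[ChannelData, Pose]]]],
    grid: ImageGrid,
    speed_of_sound: float = 1500.0,
    weights: WeightingSpec | None = None,
) -> Volume:
    """Stack independently reconstructed elevational slices into a volume.

    ``per_slice_views`` maps strictly increasing y positions to the views
    acquired with the array at that elevation.
    """
    if not per_slice_views:
        raise InvalidParameterError("need at least one slice")
    ys = np.array([y for y, _ in per_slice_views], dtype=float)
    if len(ys) > 1 and not np.all(np.diff(ys) > 0):
        raise InvalidParameterError("slice y positions must be strictly increasing")
    slices = [
        multi_view_reconstruct(views, grid, speed_of_sound, weights).values
        for _, views in per_slice_views
    ]
    return Volume(np.stack(slices, axis=0), grid, ys)


def locate_peak(image: Image) -> Peak:
    """Position and signed amplitude of the |value| maximum, refined to
    sub-pixel precision by a separable quadratic fit.

    Ties break deterministically toward the smallest z, then smallest x
    (row-major argmax order).  All-zero images raise :class:`NoPeakError`.
    """
    mag = np.abs(image.values)
    if not np.any(mag > 0):
        raise NoPeakError("image has no nonzero pixel")
    flat = int(np.argmax(mag))
    iz, ix = np.unravel_index(flat, mag.shape)
    x = image.grid.x[ix] + _parabolic_offset(mag[iz, :], ix) * image.grid.pixel_spacing
    z = image.grid.z[iz] + _parabolic_offset(mag[:, ix], iz) * image.grid.pixel_spacing
    return Peak(x=float(x), z=float(z), amplitude=float(image.values[iz, ix]))


def _parabolic_offset(profile: np.ndarray, i: int) -> float:
    """Vertex offset in [-0.5, 0.5] of the parabola through points i-1..i+1."""
    if i <= 0 or i >= len(profile) - 1:
        return 0.0
    a, b, c = profile[i - 1], profile[i], profile[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def feature_extent(image: Image, threshold_fraction: float = 0.5) -> tuple[float, float]:
    """Bounding-box extents (dx, dz) in meters of the connected component of
    above-threshold |values| containing the global peak.

    The threshold is ``threshold_fraction`` of the |value| maximum; 8-connected
    components.  A single above-threshold pixel has extent one pixel spacing
    in each axis.
    """
    if not 0 < threshold_fraction < 1:
        raise InvalidParameterError("threshold_fraction must lie in (0, 1)")
    mag = np.abs(image.values)
    peak = mag.max()
    if peak == 0:
        raise NoPeakError("image has no nonzero pixel")
    mask = mag >= threshold_fraction * peak
    labels, _ = _cc_label(mask, structure=np.ones((3, 3), dtype=int))
    iz, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    comp = labels == labels[iz, ix]
    rows = np.any(comp, axis=1).nonzero()[0]
    cols = np.any(comp, axis=0).nonzero()[0]
    sp = image.grid.pixel_spacing
    dz = (rows[-1] - rows[0] + 1) * sp
    dx = (cols[-1] - cols[0] + 1) * sp
    return float(dx), float(dz)


def lateral_fwhm(image: Image) -> float:
    """Full width at half maximum (m) of the |value| lateral profile through
    the peak row, with linear interpolation of the half crossings."""
    mag = np.abs(image.values)
    if not np.any(mag > 0):
        raise NoPeakError("image has no nonzero pixel")
    iz, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    profile = mag[iz, :]
    half = profile[ix] / 2.0
    left = ix
    while left > 0 and profile[left - 1] >= half:
        left -= 1
    right = ix
    while right < len(profile) - 1 and profile[right + 1] >= half:
        right += 1
    x_left = float(left)
    if left > 0 and profile[left] != profile[left - 1]:
        x_left = left - (profile[left] - half) / (profile[left] - profile[left - 1])
    x_right = float(right)
    if right < len(profile) - 1 and profile[right] != profile[right + 1]:
        x_right = right + (profile[right] - half) / (profile[right] - profile[right + 1])
    return float((x_right - x_left) * image.grid.pixel_spacing)
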