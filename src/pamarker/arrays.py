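"""Transducer array geometries and rigid poses.

Two receive apertures are modeled: a 128-element linear array (handheld
probe, 5 MHz center frequency, 70% fractional bandwidth) and a half-ring
arc array (55 mm radius, 178 deg span) used for multi-angle tomography.
Elements are ideal points with a position and an inward unit normal in the
imaging (x, z) plane; x is lateral, z is depth (positive into tissue), and
the elevation axis y is orthogonal to the imaging plane.  All lengths are
meters, all angles radians unless a function name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ArrayGeometry",
    "Pose",
    "make_linear_array",
    "make_arc_array",
    "apply_pose",
    "concatenate_geometries",
]


@dataclass(eq=False)
class ArrayGeometry:
    """Element positions/normals of a receive aperture.

    ``element_positions`` and ``element_normals`` are ``(n, 2)`` arrays of
    (x, z) coordinates in meters / unit vectors.  ``elevation`` is the y
    coordinate shared by all elements (the array sits in one elevational
    plane); it is advanced by the scan stage when acquiring 3D stacks.
    ``pitch_or_radius`` stores the element pitch for linear arrays and the
    arc radius for arc arrays.
    """

    kind: str  # "linear" | "arc" | "composite"
    element_positions: np.ndarray
    element_normals: np.ndarray
    center_frequency: float
    fractional_bandwidth: float
    pitch_or_radius: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        self.element_positions = np.atleast_2d(
            np.asarray(self.element_positions, dtype=float)
        )
        self.element_normals = np.atleast_2d(
            np.asarray(self.element_normals, dtype=float)
        )
        if self.element_positions.shape != self.element_normals.shape:
            raise InvalidParameterError(
                "element_positions and element_normals must have the same shape"
            )
        if self.element_positions.shape[0] < 1:
            raise InvalidParameterError("geometry needs at least one element")
        norms = np.linalg.norm(self.element_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidParameterError("element normals must be unit length")

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    def positions_3d(self) -> np.ndarray:
        """Element positions as (n, 3) arrays of (x, y, z)."""
        pos = np.empty((self.n_elements, 3))
        pos[:, 0] = self.element_positions[:, 0]
        pos[:, 1] = self.elevation
        pos[:, 2] = self.element_positions[:, 1]
        return pos


@dataclass(frozen=True)
class Pose:
    """Rigid transform: rotation about the elevation (y) axis then translation.

    ``rotation_angle`` is in radians; ``translation`` is an (x, y, z) vector
    in meters.  Applied to a point p = (x, z): p' = R(angle) p + (tx, tz),
    with the y translation advancing the array's elevational plane.
    """

    rotation_angle: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not math.isfinite(self.rotation_angle):
            raise InvalidParameterError("rotation_angle must be finite")
        object.__setattr__(self, "translation", tuple(float(t) for t in self.translation))
        if len(self.translation) != 3:
            raise InvalidParameterError("translation must be a 3-vector")

    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation in the (x, z) plane; +angle takes (+x) toward (+z)."""
        c, s = math.cos(self.rotation_angle), math.sin(self.rotation_angle)
        return np.array([[c, -s], [s, c]])

    def apply_points(self, points_xz: np.ndarray) -> np.ndarray:
        rot = self.rotation_matrix()
        out = points_xz @ rot.T
        out[:, 0] += self.translation[0]
        out[:, 1] += self.translation[2]
        return out

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        rot = self.rotation_matrix()
        t_other = np.array([other.translation[0], other.translation[2]])
        t_xz = rot @ t_other + np.array([self.translation[0], self.translation[2]])
        ty = self.translation[1] + other.translation[1]
        return Pose(
            rotation_angle=self.rotation_angle + other.rotation_angle,
            translation=(t_xz[0], ty, t_xz[1]),
        )

    def inverse(self) -> "Pose":
        rot_inv = Pose(rotation_angle=-self.rotation_angle).rotation_matrix()
        t_xz = -(rot_inv @ np.array([self.translation[0], self.translation[2]]))
        return Pose(
            rotation_angle=-self.rotation_angle,
            translation=(t_xz[0], -self.translation[1], t_xz[1]),
        )


def make_linear_array(
    n_elements: int = 128,
    pitch: float = 0.3e-3,
    center_frequency: float = 5e6,
    fractional_bandwidth: float = 0.7,
) -> ArrayGeometry:
    """Linear array centered on the origin, face at z = 0, looking into +z.

    The defaults give the handheld probe: 128 elements at 0.3 mm pitch
    (38.1 mm aperture), 5 MHz, 70% −6 dB bandwidth.
    """
    if n_elements < 1:
        raise InvalidParameterError("n_elements must be >= 1")
    if pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    if center_frequency <= 0:
        raise InvalidParameterError("center_frequency must be positive")
    if not 0 < fractional_bandwidth < 2:
        raise InvalidParameterError("fractional_bandwidth must lie in (0, 2)")
    x = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
    positions = np.column_stack([x, np.zeros_like(x)])
    normals = np.tile([0.0, 1.0], (n_elements, 1))
    return ArrayGeometry(
        kind="linear",
        element_positions=positions,
        element_normals=normals,
        center_frequency=center_frequency,
        fractional_bandwidth=fractional_bandwidth,
        pitch_or_radius=pitch,
    )


def make_arc_array(
    radius: float = 55e-3,
    span: float = 178.0,
    n_elements: int = 128,
    center_frequency: float = 5e6,
    fractional_bandwidth: float = 0.7,
) -> ArrayGeometry:
    """Arc array on a circle centered at the origin, normals pointing inward.

    ``span`` is in degrees.  Elements are spread symmetrically about the +z
    axis: element angles theta_j in [-span/2, +span/2] measured from +z, at
    positions (R sin theta, R cos theta).  The imaging region is the
    neighborhood of the circle center.  Defaults give the half-ring
    tomography array: 55 mm radius, 178 deg, 128 elements.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    if not 0 < span <= 360:
        raise InvalidParameterError("span must lie in (0, 360] degrees")
    if n_elements < 1:
        raise InvalidParameterError("n_elements must be >= 1")
    if center_frequency <= 0:
        raise InvalidParameterError("center_frequency must be positive")
    half = math.radians(span) / 2.0
    if n_elements == 1:
        thetas = np.array([0.0])
    else:
        thetas = np.linspace(-half, half, n_elements)
    positions = np.column_stack([radius * np.sin(thetas), radius * np.cos(thetas)])
    normals = -positions / radius
    return ArrayGeometry(
        kind="arc",
        element_positions=positions,
        element_normals=normals,
        center_frequency=center_frequency,
        fractional_bandwidth=fractional_bandwidth,
        pitch_or_radius=radius,
    )


def apply_pose(geometry: ArrayGeometry, pose: Pose) -> ArrayGeometry:
    """Rigidly transform a geometry: positions rotated then translated,
    normals rotated only, elevation advanced by the y translation."""
    rot = pose.rotation_matrix()
    positions = pose.apply_points(geometry.element_positions.copy())
    normals = geometry.element_normals @ rot.T
    return replace(
        geometry,
        element_positions=positions,
        element_normals=normals,
        elevation=geometry.elevation + pose.translation[1],
    )


def concatenate_geometries(geometries: list[ArrayGeometry]) -> ArrayGeometry:
    """Union of several apertures as one composite geometry.

    Used by multi-angle joint reconstruction; the composite keeps the first
    geometry's frequency metadata.  All geometries must share one
    elevational plane.
    """
    if not geometries:
        raise InvalidParameterError("need at least one geometry")
    first = geometries[0]
    elevs = {g.elevation for g in geometries}
    if len(elevs) > 1:
        raise InvalidParameterError("cannot concatenate geometries at different elevations")
    return ArrayGeometry(
        kind="composite",
        element_positions=np.vstack([g.element_positions for g in geometries]),
        element_normals=np.vstack([g.element_normals for g in geometries]),
        center_frequency=first.center_frequency,
        fractional_bandwidth=first.fractional_bandwidth,
        pitch_or_radius=first.pitch_or_radius,
        elevation=first.elevation,
    )
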