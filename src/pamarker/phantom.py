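"""Synthetic phantoms: titanium marker clips, vessel-like absorbers,
speckle-generating scatterers, and a depth-attenuating optical medium.

The marker clip is a 1 mm (diameter) x 3 mm (length) titanium cylinder with
an optional hooked tail, discretized into a lattice of point absorbers on
its surface and axis.  Three canonical orientations relative to the imaging
plane are supported:

* ``in_plane_parallel``    — cylinder axis along the lateral (x) axis;
* ``perpendicular_to_plane`` — axis along the elevation (y) axis, so the
  in-plane cross-section is a point-like 1 mm disc;
* ``in_plane_vertical``    — axis along the depth (z) axis.

Optical fluence decays exponentially with depth with effective attenuation
``mu_eff`` (default 40 m^-1, i.e. 0.4 cm^-1, the value of a 3% agarose /
1% Intralipid phantom).  Photoacoustic amplitudes are relative initial
pressures normalized so titanium = 1 and blood = 0.91, the measured ratio of
~1.09 between the two materials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Absorber",
    "Scatterer",
    "OpticalModel",
    "MarkerSpec",
    "Phantom",
    "amplitude_preset",
    "fluence_at",
    "make_marker",
    "marker_scatterers",
    "make_marker_phantom",
    "make_depth_series",
    "make_tissue_background",
]

#: Relative initial-pressure presets; titanium is ~1.09x blood.
_AMPLITUDE_PRESETS = {"titanium": 1.0, "blood": 0.91}

ORIENTATIONS = ("in_plane_parallel", "perpendicular_to_plane", "in_plane_vertical")


@dataclass(frozen=True)
class Absorber:
    """Point photoacoustic source: 3D position (m), relative initial
    pressure, and radius (0 = ideal point)."""

    position: tuple[float, float, float]
    amplitude: float
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidParameterError("absorber amplitude must be >= 0")
        if self.radius < 0:
            raise InvalidParameterError("absorber radius must be >= 0")


@dataclass(frozen=True)
class Scatterer:
    """Point ultrasound scatterer: 3D position (m) and reflectivity >= 0."""

    position: tuple[float, float, float]
    reflectivity: float

    def __post_init__(self) -> None:
        if self.reflectivity < 0:
            raise InvalidParameterError("scatterer reflectivity must be >= 0")


@dataclass(frozen=True)
class OpticalModel:
    """1D exponential fluence model: phi(z) = surface_fluence * exp(-mu_eff z)."""

    mu_eff: float = 40.0  # 1/m  (0.4 cm^-1)
    surface_fluence: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_eff < 0:
            raise InvalidParameterError("mu_eff must be >= 0")


@dataclass(frozen=True)
class MarkerSpec:
    """Geometry of the marker-clip absorber cloud."""

    depth: float = 15e-3
    orientation: str = "in_plane_parallel"
    length: float = 3e-3
    diameter: float = 1e-3
    with_hook: bool = True
    sample_spacing: float = 0.1e-3

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidParameterError("marker length and diameter must be positive")
        if not 0 < self.sample_spacing <= self.length:
            raise InvalidParameterError(
                "sample_spacing must lie in (0, length]"
            )
        if self.orientation not in ORIENTATIONS:
            raise InvalidParameterError(
                f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}"
            )


@dataclass
class Phantom:
    """A collection of PA absorbers and US scatterers in an attenuating medium."""

    absorbers: list[Absorber] = field(default_factory=list)
    scatterers: list[Scatterer] = field(default_factory=list)
    optics: OpticalModel = field(default_factory=OpticalModel)
    speed_of_sound: float = 1500.0

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise InvalidParameterError("speed_of_sound must be positive")

    def absorber_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, 3) positions and (n,) amplitudes as dense arrays."""
        if not self.absorbers:
            return np.zeros((0, 3)), np.zeros(0)
        pos = np.array([a.position for a in self.absorbers], dtype=float)
        amp = np.array([a.amplitude for a in self.absorbers], dtype=float)
        return pos, amp

    def scatterer_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.scatterers:
            return np.zeros((0, 3)), np.zeros(0)
        pos = np.array([s.position for s in self.scatterers], dtype=float)
        ref = np.array([s.reflectivity for s in self.scatterers], dtype=float)
        return pos, ref

    def source_table(self) -> np.ndarray:
        """All sources as rows (x, y, z, amplitude) for delimited export;
        scatterers follow absorbers."""
        apos, aamp = self.absorber_arrays()
        spos, sref = self.scatterer_arrays()
        return np.vstack(
            [
                np.column_stack([apos, aamp]) if len(aamp) else np.zeros((0, 4)),
                np.column_stack([spos, sref]) if len(sref) else np.zeros((0, 4)),
            ]
        )


def amplitude_preset(material: str) -> float:
    """Relative initial pressure of a material: titanium -> 1.0, blood -> 0.91."""
    try:
        return _AMPLITUDE_PRESETS[material]
    except KeyError:
        raise InvalidParameterError(
            f"unknown material {material!r}; expected one of {sorted(_AMPLITUDE_PRESETS)}"
        ) from None


def fluence_at(optics: OpticalModel, depth):
    """Relative optical fluence at a depth (m): surface_fluence * exp(-mu_eff z).

    Accepts scalars or arrays; negative depths are a contract violation.
    """
    depth_arr = np.asarray(depth, dtype=float)
    if np.any(depth_arr < 0):
        raise InvalidParameterError("depth must be >= 0")
    out = optics.surface_fluence * np.exp(-optics.mu_eff * depth_arr)
    return float(out) if np.isscalar(depth) or depth_arr.ndim == 0 else out


def _canonical_marker_cloud(spec: MarkerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lattice of points for a marker with axis along +x, centered at origin.

    Points sit on the cylinder surface and axis at ``sample_spacing``: rings
    at spacing along the axis, each ring carrying equally spaced surface
    points plus one axis point.  The optional hook is a quarter-circle tail
    of radius 0.5 mm continuing tangentially from the +x end.

    Returns (points, normals): outward surface unit normals for lateral
    surface points, zero vectors for axis/hook (interior-like) points.  The
    normals feed the specular echogenicity model of
    :func:`marker_scatterers`; they play no role in optical absorption.
    """
    ds = spec.sample_spacing
    length, radius = spec.length, spec.diameter / 2.0
    n_rings = int(round(length / ds)) + 1
    xs = np.linspace(-length / 2.0, length / 2.0, n_rings)
    n_circ = max(3, int(round(math.pi * spec.diameter / ds)))
    phis = 2.0 * math.pi * np.arange(n_circ) / n_circ
    pts, nrm = [], []
    for x in xs:
        pts.append([x, 0.0, 0.0])  # axis point
        nrm.append([0.0, 0.0, 0.0])
        for phi in phis:
            pts.append([x, radius * math.cos(phi), radius * math.sin(phi)])
            nrm.append([0.0, math.cos(phi), math.sin(phi)])
    if spec.with_hook:
        hook_r = 0.5e-3
        arc_len = 0.5 * math.pi * hook_r
        n_hook = max(1, int(round(arc_len / ds)))
        for j in range(1, n_hook + 1):
            t = 0.5 * math.pi * j / n_hook
            pts.append(
                [length / 2.0 + hook_r * math.sin(t), 0.0, hook_r * (1.0 - math.cos(t))]
            )
            nrm.append([0.0, 0.0, 0.0])
    return np.array(pts), np.array(nrm)


_ORIENTATION_ROTATIONS = {
    # maps the canonical +x axis to the requested direction
    "in_plane_parallel": np.eye(3),
    # axis -> +y (elevation): rotate about z by +90 deg
    "perpendicular_to_plane": np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
    # axis -> +z (depth): rotate about y by -90 deg
    "in_plane_vertical": np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]),
}


def make_marker(spec: MarkerSpec) -> list[Absorber]:
    """Discretize the marker clip into point absorbers at the titanium preset.

    All orientations are rigid rotations of one canonical cloud, so absorber
    count and total amplitude are orientation-independent.  The cloud is
    centered at (0, 0, depth).
    """
    cloud, _ = _canonical_marker_cloud(spec)
    rot = _ORIENTATION_ROTATIONS[spec.orientation]
    cloud = cloud @ rot.T
    cloud[:, 2] += spec.depth
    amp = amplitude_preset("titanium")
    return [Absorber(position=tuple(p), amplitude=amp) for p in cloud]


def marker_scatterers(
    spec: MarkerSpec,
    reflectivity: float = 1.0,
    diffuse_fraction: float = 0.1,
    probe_direction: tuple[float, float, float] = (0.0, 0.0, -1.0),
) -> list[Scatterer]:
    """US scatterers for the marker's smooth metal surface.

    Monostatic echoes from a polished titanium surface are dominated by
    specular reflection: only surface patches whose outward normal points
    back at the probe return energy.  Per-point reflectivity is

        R = reflectivity * (diffuse + (1 - diffuse) * max(0, n . v)^2)

    with v the unit direction from tissue toward the probe (default -z for
    the handheld top-down geometry) and n the outward surface normal; axis
    and hook points carry only the diffuse floor.  This makes a cylinder
    lying parallel to the array strongly echogenic along its top strip while
    a vertical cylinder (normals orthogonal to the beam) returns little —
    the marker is then faint in US even though its PA appearance is bright.
    """
    if not 0 <= diffuse_fraction <= 1:
        raise InvalidParameterError("diffuse_fraction must lie in [0, 1]")
    cloud, normals = _canonical_marker_cloud(spec)
    rot = _ORIENTATION_ROTATIONS[spec.orientation]
    cloud = cloud @ rot.T
    normals = normals @ rot.T
    cloud[:, 2] += spec.depth
    v = np.asarray(probe_direction, dtype=float)
    v = v / np.linalg.norm(v)
    alignment = np.clip(normals @ v, 0.0, None)
    refl = reflectivity * (diffuse_fraction + (1.0 - diffuse_fraction) * alignment**2)
    return [
        Scatterer(position=tuple(p), reflectivity=float(r))
        for p, r in zip(cloud, refl)
    ]


def make_marker_phantom(
    spec: MarkerSpec,
    optics: OpticalModel | None = None,
    speed_of_sound: float = 1500.0,
    include_us_scatterers: bool = False,
    reflectivity: float = 1.0,
) -> Phantom:
    """Phantom containing one marker; optionally with the specular-surface
    US scatterer model of :func:`marker_scatterers`."""
    absorbers = make_marker(spec)
    scatterers = (
        marker_scatterers(spec, reflectivity=reflectivity)
        if include_us_scatterers
        else []
    )
    return Phantom(
        absorbers=absorbers,
        scatterers=scatterers,
        optics=optics if optics is not None else OpticalModel(),
        speed_of_sound=speed_of_sound,
    )


def make_depth_series(
    depths,
    orientation: str = "in_plane_parallel",
    spec: MarkerSpec | None = None,
    optics: OpticalModel | None = None,
    speed_of_sound: float = 1500.0,
    include_us_scatterers: bool = False,
) -> list[Phantom]:
    """One marker phantom per depth, identical apart from the burial depth.

    The default depths study is 5/15/25/35 mm.
    """
    depths = list(depths)
    if not depths:
        raise InvalidParameterError("depths must be non-empty")
    if any(d <= 0 for d in depths):
        raise InvalidParameterError("all depths must be positive")
    base = spec if spec is not None else MarkerSpec()
    phantoms = []
    for d in depths:
        s = MarkerSpec(
            depth=d,
            orientation=orientation,
            length=base.length,
            diameter=base.diameter,
            with_hook=base.with_hook,
            sample_spacing=base.sample_spacing,
        )
        phantoms.append(
            make_marker_phantom(
                s,
                optics=optics,
                speed_of_sound=speed_of_sound,
                include_us_scatterers=include_us_scatterers,
            )
        )
    return phantoms


def make_tissue_background(
    region,
    vessel_count: int,
    scatterer_density: float,
    seed: int,
) -> Phantom:
    """Random tissue-like background in a 2D region of the imaging plane.

    ``region`` is (x_min, x_max, z_min, z_max) in meters.  Blood vessels in
    cross-section are point absorbers at the blood amplitude preset;
    fascia-like echogenic texture is a Poisson field of point scatterers of
    Rayleigh-distributed reflectivity with expected count
    ``scatterer_density * area`` (density in 1/m^2).  Fully reproducible for
    a fixed seed.
    """
    x_min, x_max, z_min, z_max = (float(v) for v in region)
    if not (x_max > x_min and z_max > z_min):
        raise InvalidParameterError("region must be non-degenerate")
    if scatterer_density < 0:
        raise InvalidParameterError("scatterer_density must be >= 0")
    if vessel_count < 0:
        raise InvalidParameterError("vessel_count must be >= 0")
    rng = np.random.default_rng(seed)
    area = (x_max - x_min) * (z_max - z_min)
    blood = amplitude_preset("blood")
    absorbers = []
    for _ in range(vessel_count):
        x = rng.uniform(x_min, x_max)
        z = rng.uniform(z_min, z_max)
        absorbers.append(Absorber(position=(x, 0.0, z), amplitude=blood))
    n_sc = int(rng.poisson(scatterer_density * area)) if scatterer_density > 0 else 0
    scatterers = []
    if n_sc:
        xs = rng.uniform(x_min, x_max, n_sc)
        zs = rng.uniform(z_min, z_max, n_sc)
        refs = rng.rayleigh(scale=0.5, size=n_sc)
        scatterers = [
            Scatterer(position=(x, 0.0, z), reflectivity=r)
            for x, z, r in zip(xs, zs, refs)
        ]
    return Phantom(absorbers=absorbers, scatterers=scatterers)
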