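"""Independent reference implementations used only to cross-check the
package: a naive per-pixel/per-element delay-and-sum loop and a by-hand
enumeration of the marker discretization lattice.  These are deliberately
written in the most literal way possible and share no code with the
package's vectorized paths."""

import math

import numpy as np


def naive_das(
    samples: np.ndarray,
    sampling_rate: float,
    t0: float,
    positions: np.ndarray,
    normals: np.ndarray,
    grid_x: np.ndarray,
    grid_z: np.ndarray,
    speed_of_sound: float,
    delay_factor: float = 1.0,
    angular_exponent: float = 1.0,
    max_angle: float = math.radians(60.0),
) -> np.ndarray:
    """Textbook triple-loop DAS: for every pixel, for every element, look up
    the linearly interpolated sample at the time of flight, weight by
    cos^q(theta) inside the acceptance cone, and normalize by the summed
    weight."""
    n_el, n_t = samples.shape
    cos_cut = math.cos(max_angle)
    image = np.zeros((len(grid_z), len(grid_x)))
    for iz, z in enumerate(grid_z):
        for ix, x in enumerate(grid_x):
            num = 0.0
            den = 0.0
            for i in range(n_el):
                dx = x - positions[i, 0]
                dz = z - positions[i, 1]
                r = math.hypot(dx, dz)
                if r == 0.0:
                    cos_theta = 1.0
                else:
                    cos_theta = (normals[i, 0] * dx + normals[i, 1] * dz) / r
                if cos_theta < cos_cut:
                    continue
                if angular_exponent == 0:
                    w = 1.0
                elif angular_exponent == 1.0:
                    w = cos_theta
                else:
                    w = cos_theta**angular_exponent
                s = (delay_factor * r / speed_of_sound - t0) * sampling_rate
                i0 = math.floor(s)
                if i0 < 0 or i0 + 1 >= n_t:
                    continue
                frac = s - i0
                num += w * (samples[i, i0] * (1.0 - frac) + samples[i, i0 + 1] * frac)
                den += w
            image[iz, ix] = num / den if den > 0 else 0.0
    return image


def enumerate_marker_lattice(
    length: float, diameter: float, sample_spacing: float, with_hook: bool
) -> int:
    """Brute-force count of the marker discretization lattice, built point
    by point from the stated rule: rings every sample_spacing along the
    axis, each with one axis point and circumference/spacing surface
    points; a quarter-circle hook of radius 0.5 mm sampled at the same
    spacing."""
    points = []
    n_rings = int(round(length / sample_spacing)) + 1
    for k in range(n_rings):
        x = -length / 2 + k * length / (n_rings - 1) if n_rings > 1 else 0.0
        points.append((x, 0.0, 0.0))
        n_circ = max(3, int(round(math.pi * diameter / sample_spacing)))
        for j in range(n_circ):
            phi = 2 * math.pi * j / n_circ
            points.append(
                (x, diameter / 2 * math.cos(phi), diameter / 2 * math.sin(phi))
            )
    if with_hook:
        n_hook = max(1, int(round(0.5 * math.pi * 0.5e-3 / sample_spacing)))
        for j in range(1, n_hook + 1):
            t = 0.5 * math.pi * j / n_hook
            points.append(
                (length / 2 + 0.5e-3 * math.sin(t), 0.0, 0.5e-3 * (1 - math.cos(t)))
            )
    return len(points)
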