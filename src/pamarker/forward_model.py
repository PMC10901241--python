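"""Band-limited forward simulation of PA and pulse-echo US channel data.

Physics, deliberately simple and fully linear:

* PA: every point absorber emits a spherical wave at laser time t = 0.
  Element i records  s_i(t) = sum_k A_k phi(z_k) (r_ref / r_ik) w(t - r_ik/c)
  where A_k is the relative initial pressure, phi the optical fluence at the
  absorber's depth, r_ik the 3D absorber-element distance, r_ref = 1 cm a
  fixed reference distance that keeps amplitudes dimensionless, and w the
  bipolar receive wavelet.

* US: monostatic pulse-echo per element (same element transmits and
  receives), so echoes arrive at the round-trip delay 2 r / c with 1/r^2
  spreading:  s_i(t) = sum_k R_k (r_ref / r_ik)^2 w_us(t - 2 r_ik/c).

No acoustic attenuation, no multiple scattering, no occlusion.  An optional
Gaussian elevational sensitivity models the acoustic lens: a source at
elevational offset dy from the array plane is weighted by
exp(-dy^2 / (2 sigma_e^2)).

The receive wavelet has its spectral magnitude peak at the transducer center
frequency and a -6 dB fractional bandwidth matching the transducer (70% for
the 5 MHz probes).  The PA shape is the antisymmetric (sine-phase) Gaussian
pulse — the band-limited analogue of the derivative-of-Gaussian N-shape
produced by an impulsive heat deposit: bipolar, odd about the arrival time,
zero exactly at the time of flight.  The US shape is the even (cosine-phase)
Gaussian pulse of a conventional transmit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .arrays import ArrayGeometry
from .errors import InvalidGeometryError, InvalidParameterError
from .phantom import Phantom, fluence_at

__all__ = [
    "AcquisitionParams",
    "Wavelet",
    "ChannelData",
    "InterferenceSpec",
    "simulate_pa_channels",
    "simulate_us_channels",
    "add_noise_and_interference",
    "suppress_common_mode",
    "highpass_filter",
]

#: Reference distance (m) at which geometric spreading has unit gain.
REFERENCE_DISTANCE = 1e-2
#: Sources closer than this to an element are geometrically degenerate.
_MIN_SOURCE_DISTANCE = 1e-6
#: −6 dB reference used for the fractional-bandwidth definition.
_BW_REF = 10.0 ** (-6.0 / 20.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling of the receive chain.

    ``t0`` is the time of sample 0 relative to the laser pulse / transmit
    event.  ``speed_of_sound`` overrides the phantom's medium speed when
    set.  ``elevation_sigma`` enables the Gaussian elevational sensitivity
    (None = ideal point elements seeing all elevations equally).
    """

    sampling_rate: float = 40e6
    n_samples: int = 2048
    t0: float = 0.0
    speed_of_sound: float | None = None
    elevation_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Wavelet:
    """Gaussian-envelope receive pulse with prescribed center frequency and
    −6 dB fractional bandwidth.

    ``shape`` selects the carrier phase: ``derivative_gaussian`` is the odd,
    bipolar PA pulse; ``gaussian_modulated_cosine`` the even US pulse.
    The peak is normalized to 1.
    """

    center_frequency: float
    fractional_bandwidth: float
    shape: str = "derivative_gaussian"

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise InvalidParameterError("center_frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise InvalidParameterError("fractional_bandwidth must lie in (0, 2)")
        if self.shape not in ("derivative_gaussian", "gaussian_modulated_cosine"):
            raise InvalidParameterError(f"unknown wavelet shape {self.shape!r}")
        # envelope exp(-a t^2) whose spectrum is -6 dB down bw*fc/2 away from fc
        half_bw = 0.5 * self.fractional_bandwidth * self.center_frequency
        self._a = (math.pi * half_bw) ** 2 / (-math.log(_BW_REF))
        # numeric peak normalization (analytic peak of env*sin is transcendental)
        t = np.linspace(-self.support_halfwidth, self.support_halfwidth, 4001)
        self._norm = 1.0
        self._norm = float(np.max(np.abs(self(t))))

    @property
    def support_halfwidth(self) -> float:
        """Half-width beyond which the envelope is < 1e-8 of its peak."""
        return math.sqrt(math.log(1e8) / self._a)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        env = np.exp(-self._a * t * t)
        carrier = 2.0 * math.pi * self.center_frequency * t
        if self.shape == "derivative_gaussian":
            out = env * np.sin(carrier)
        else:
            out = env * np.cos(carrier)
        return out / self._norm


@dataclass
class ChannelData:
    """Raw RF channel data: samples[element, time] plus sampling metadata."""

    samples: np.ndarray
    sampling_rate: float
    t0: float
    modality: str  # "PA" | "US"
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidParameterError("samples must be a 2D [elements x time] array")
        if self.samples.shape[0] != self.geometry.n_elements:
            raise InvalidParameterError(
                "samples row count must equal the geometry's element count"
            )
        if self.modality not in ("PA", "US"):
            raise InvalidParameterError("modality must be 'PA' or 'US'")

    @property
    def n_elements(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "ChannelData":
        return replace(self, samples=self.samples.copy())


@dataclass(frozen=True)
class InterferenceSpec:
    """Additive channel noise plus common-mode RF interference bursts.

    Each burst is one carrier cycle of the PA wavelet added *identically* to
    every channel at the stated time — the software analogue of unshielded
    pulsed-RF pickup, which beamforms into a sharp horizontal line.
    """

    burst_times: tuple[float, ...] = ()
    burst_amplitude: float = 0.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_amplitude < 0 or self.noise_std < 0:
            raise InvalidParameterError("amplitudes must be >= 0")
        object.__setattr__(self, "burst_times", tuple(float(t) for t in self.burst_times))


def _effective_sound_speed(phantom: Phantom, acq: AcquisitionParams) -> float:
    return acq.speed_of_sound if acq.speed_of_sound is not None else phantom.speed_of_sound


def _check_sampling(geometry: ArrayGeometry, acq: AcquisitionParams) -> None:
    limit = 2.0 * geometry.center_frequency * (1.0 + geometry.fractional_bandwidth)
    if acq.sampling_rate <= limit:
        raise InvalidParameterError(
            f"sampling_rate {acq.sampling_rate:g} Hz does not cover the transducer "
            f"band (needs > {limit:g} Hz)"
        )


def _elevation_weights(dy: np.ndarray, sigma: float | None) -> np.ndarray:
    if sigma is None:
        return np.ones_like(dy)
    return np.exp(-(dy * dy) / (2.0 * sigma * sigma))


def _warn_behind_array(positions: np.ndarray, geometry: ArrayGeometry) -> None:
    center = geometry.element_positions.mean(axis=0)
    normal = geometry.element_normals.mean(axis=0)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:  # opposing normals (wide arc): no meaningful array plane
        return
    normal = normal / nn
    rel = positions[:, [0, 2]] - center
    if np.any(rel @ normal < 0):
        warnings.warn(
            "some sources lie behind the array plane; they are included "
            "(no occlusion model)",
            stacklevel=3,
        )


def _simulate(
    positions: np.ndarray,
    strengths: np.ndarray,
    geometry: ArrayGeometry,
    acq: AcquisitionParams,
    wavelet: Wavelet,
    c: float,
    delay_factor: float,
    spreading_exponent: int,
) -> np.ndarray:
    """Windowed superposition of per-source wavelets onto the sample grid."""
    n_el, n_t = geometry.n_elements, acq.n_samples
    out = np.zeros((n_el, n_t))
    if len(strengths) == 0:
        return out
    elems = geometry.positions_3d()
    fs = acq.sampling_rate
    w_half = int(math.ceil(wavelet.support_halfwidth * fs)) + 1
    offsets = np.arange(-w_half, w_half + 1)
    weights = _elevation_weights(positions[:, 1] - geometry.elevation, acq.elevation_sigma)
    eff = strengths * weights
    for i in range(n_el):
        d = positions - elems[i]
        r = np.sqrt(np.einsum("kj,kj->k", d, d))
        if np.any(r < _MIN_SOURCE_DISTANCE):
            raise InvalidGeometryError("source coincides with an element position")
        tau = delay_factor * r / c
        amp = eff * (REFERENCE_DISTANCE / r) ** spreading_exponent
        center_idx = np.rint((tau - acq.t0) * fs).astype(int)
        idx = center_idx[:, None] + offsets[None, :]
        t = acq.t0 + idx / fs - tau[:, None]
        vals = amp[:, None] * wavelet(t)
        valid = (idx >= 0) & (idx < n_t)
        idx_flat, vals_flat = idx[valid], vals[valid]
        # canonical accumulation order: channels are bitwise independent of
        # the source list ordering
        order = np.lexsort((vals_flat, idx_flat))
        np.add.at(out[i], idx_flat[order], vals_flat[order])
    return out


def simulate_pa_channels(
    phantom: Phantom,
    geometry: ArrayGeometry,
    acq: AcquisitionParams,
    wavelet: Wavelet | None = None,
) -> ChannelData:
    """Photoacoustic channel data from the phantom's absorbers.

    Amplitudes scale linearly with absorber amplitude and with the optical
    fluence at the absorber's depth; geometric spreading is 1/r (spherical
    emission).  Sources nominally above the tissue surface (z < 0, possible
    in the water-coupled ring geometry) see the unattenuated surface fluence.
    """
    _check_sampling(geometry, acq)
    c = _effective_sound_speed(phantom, acq)
    if wavelet is None:
        wavelet = Wavelet(
            geometry.center_frequency, geometry.fractional_bandwidth, "derivative_gaussian"
        )
    positions, amplitudes = phantom.absorber_arrays()
    if len(amplitudes):
        _warn_behind_array(positions, geometry)
        depths = np.clip(positions[:, 2], 0.0, None)
        strengths = amplitudes * fluence_at(phantom.optics, depths)
    else:
        strengths = amplitudes
    samples = _simulate(positions, strengths, geometry, acq, wavelet, c, 1.0, 1)
    return ChannelData(samples, acq.sampling_rate, acq.t0, "PA", geometry)


def simulate_us_channels(
    phantom: Phantom,
    geometry: ArrayGeometry,
    acq: AcquisitionParams,
    wavelet: Wavelet | None = None,
) -> ChannelData:
    """Monostatic pulse-echo channel data from the phantom's scatterers.

    Round-trip delay 2r/c and 1/r^2 spreading; linear in reflectivity.
    """
    _check_sampling(geometry, acq)
    c = _effective_sound_speed(phantom, acq)
    if wavelet is None:
        wavelet = Wavelet(
            geometry.center_frequency,
            geometry.fractional_bandwidth,
            "gaussian_modulated_cosine",
        )
    positions, reflectivities = phantom.scatterer_arrays()
    if len(reflectivities):
        _warn_behind_array(positions, geometry)
    samples = _simulate(positions, reflectivities, geometry, acq, wavelet, c, 2.0, 2)
    return ChannelData(samples, acq.sampling_rate, acq.t0, "US", geometry)


def add_noise_and_interference(
    channels: ChannelData, spec: InterferenceSpec
) -> ChannelData:
    """Add i.i.d. Gaussian sample noise and common-mode interference bursts.

    Bursts are identical across channels by definition of common mode;
    bursts outside the record are ignored with a warning.  Reproducible for
    a fixed seed.
    """
    out = channels.copy()
    if spec.burst_amplitude > 0 and spec.burst_times:
        geom = channels.geometry
        wav = Wavelet(
            geom.center_frequency, geom.fractional_bandwidth, "derivative_gaussian"
        )
        t = channels.times()
        period = 1.0 / geom.center_frequency
        t_min, t_max = t[0], t[-1]
        for tb in spec.burst_times:
            if tb < t_min or tb > t_max:
                warnings.warn(f"burst time {tb:g} s outside the record; ignored")
                continue
            dt = t - tb
            burst = np.where(np.abs(dt) <= period / 2.0, wav(dt), 0.0)
            out.samples += spec.burst_amplitude * burst[None, :]
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        out.samples += rng.normal(0.0, spec.noise_std, out.samples.shape)
    return out


def suppress_common_mode(channels: ChannelData) -> ChannelData:
    """Subtract the across-element mean at every time sample.

    Removes any component shared identically by all channels (the RF
    interference) while perturbing spatially diverse echoes only slightly
    for large element counts.
    """
    if channels.n_elements < 2:
        raise InvalidParameterError("common-mode suppression needs >= 2 elements")
    out = channels.copy()
    out.samples -= out.samples.mean(axis=0, keepdims=True)
    return out


def highpass_filter(channels: ChannelData, cutoff: float = 0.5e6) -> ChannelData:
    """Zero-phase 4th-order Butterworth high-pass along the time axis.

    Removes low-frequency noise and DC drift ahead of reconstruction;
    forward-backward application keeps arrival times unshifted.
    """
    nyquist = channels.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise InvalidParameterError(
            f"cutoff must lie in (0, Nyquist={nyquist:g}) Hz"
        )
    sos = butter(4, cutoff, btype="highpass", fs=channels.sampling_rate, output="sos")
    out = channels.copy()
    out.samples = sosfiltfilt(sos, out.samples, axis=1)
    return out
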