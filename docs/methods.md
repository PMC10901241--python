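# Methods

This note records the physical model behind `pamarker`, the defaults and
why they were chosen, and what the synthetic experiments do and do not
demonstrate about real marker-clip imaging.

## Coordinate conventions and units

x is lateral (along the linear array), z is depth (positive into tissue),
y is the elevation/scan axis. The origin sits at the center of the array
face for the linear probe, and at the ring center for the arc array. All
internal quantities are SI (meters, seconds, Hz); the run-config interface
uses millimeters and MHz because that is how operators think about these
systems.

## Phantoms

**Marker clip.** The clip is discretized as a lattice of ideal point
absorbers at `sample_spacing` (default 0.1 mm): rings every spacing along
the 3 mm axis, each ring carrying one axis point plus equally spaced
points on the 1 mm-diameter surface. The optional hook is a quarter-circle
tail of radius 0.5 mm continuing tangentially from one end; the physical
hook is visible in product photographs but not dimensioned anywhere, so
the radius is a plausibility choice. All absorbers share the titanium
amplitude preset — nothing is known about absorption variation along the
wire, so uniformity is the neutral assumption. The three canonical
orientations are rigid rotations of one canonical cloud, which guarantees
orientation-independent absorber count and total amplitude by
construction. Note the hook breaks the cylinder's mirror symmetry: with
`with_hook=True` the cloud centroid sits slightly beyond the nominal
depth, and the reconstructed peak typically lands on the hook, where
absorbing material is locally densest.

**Amplitude presets.** Titanium = 1, blood = 0.91, a relative initial
pressure ratio of ≈1.099. These are the measured, averaged reconstruction
intensities of a titanium wire and bovine blood under identical
illumination; the toolkit treats them as ground-truth source amplitudes
and verifies that linear reconstruction carries the ratio into the image
unchanged.

**Optical fluence.** A 1D exponential `φ(z) = φ₀ exp(−μ_eff z)` with
μ_eff = 0.4 cm⁻¹ (3% agarose / 1% Intralipid). A diffusion or Monte-Carlo
solution would change the near-surface profile but not the monotone depth
decay, which is the only feature the depth-series experiment relies on;
only μ_eff is known, so the single-parameter model is the honest one.
Sources nominally above the surface (z < 0, possible in the water-coupled
ring geometry) see the unattenuated surface fluence — attenuation is
clamped at zero depth rather than extrapolated.

**Marker echogenicity in US.** Pulse-echo visibility of the clip is
modeled by placing scatterers on the same lattice with reflectivity

    R = diffuse + (1 − diffuse) · max(0, n·v)²,  diffuse = 0.1,

where n is the outward surface normal and v the unit direction toward the
probe. A polished metal surface is predominantly a specular reflector: in
monostatic operation only patches whose normal points back at the element
return appreciable energy. The consequence — deliberate, and matching
bench experience — is that a clip lying parallel to the array is strongly
echogenic along its top strip, while a vertically oriented clip (normals
orthogonal to the beam) returns little more than the diffuse floor and
fades into the background, even though its photoacoustic signature remains
bright. With purely isotropic scatterers this ordering actually inverts,
because the vertical clip's near tip wins on 1/r² proximity. Tissue
scatterers stay isotropic (Rayleigh-distributed reflectivity, Poisson
count with mean density × area): speckle is diffuse by nature.

**Vessels.** Blood vessels appear in cross-section as point absorbers at
the blood preset — exactly the "small round feature" that a marker clip
can be confused with, which is the clinical motivation for dual-modality
confirmation.

## Forward model

Each point absorber emits a spherical wave at the laser instant t = 0;
element i records

    sᵢ(t) = Σₖ Aₖ φ(zₖ) (r_ref / rᵢₖ) w(t − rᵢₖ/c),

with r_ref = 1 cm a fixed reference distance that keeps amplitudes
dimensionless. US is monostatic pulse-echo per element: delay 2r/c,
spreading (r_ref/r)². There is no acoustic attenuation, occlusion,
multiple scattering, or diffraction — the model is exactly linear in
source amplitude, which is both its main limitation and the property the
contrast-preservation tests exercise.

**Receive wavelet.** A Gaussian-envelope pulse whose spectral magnitude
peaks exactly at the transducer center frequency (5 MHz) with a −6 dB
fractional bandwidth of 70%. The PA shape is the *sine-phase*
(antisymmetric) pulse: bipolar, odd about the arrival time, with its zero
crossing exactly at the time of flight — the band-limited analogue of the
derivative-of-Gaussian N-shape of an impulsive thermoelastic source. A
literal one-parameter derivative of a Gaussian was rejected because its
−6 dB fractional bandwidth is fixed near 160% and cannot represent a 70%
transducer. The US transmit uses the even cosine-phase twin. One practical
consequence of the odd PA pulse: a point source reconstructs as a
positive/negative lobe pair with a null at the true position, so the
|amplitude| peak sits about a quarter wavelength (~75 µm) off — which is
why localization is asserted to one wavelength, not one pixel.

**Sampling.** 40 MHz, 2048 samples (51.2 µs, i.e. ~77 mm one-way at
1500 m/s) — comfortably covering the 40 mm imaging depth; neither value is
published for the actual DAQ, so both are declared defaults, checked
against the transducer band (fs > 2 f_c (1 + bw)).

**Interference.** Common-mode RF pickup is one carrier cycle of the PA
wavelet added *identically* to every channel at each burst time —
identical by the definition of common mode. After beamforming this
produces the characteristic near-full-width horizontal line at z ≈ c·t_b.
Software suppression subtracts the across-element mean per time sample,
which removes the common component exactly while perturbing a spatially
diverse point-source signal by only a few percent at 128 channels (the
point's contribution to the mean is ~1/N per channel). Channel noise is
i.i.d. Gaussian, seeded.

**Elevational sensitivity.** Optionally, a source at elevational offset dy
from the array plane is weighted `exp(−dy²/2σ_e²)`. σ_e = 0.5 mm is used
by the 3D presets as a stand-in for the elevational lens (2 cm focus) and
ring focal geometry; with ideal point elements and no weighting, every
slice of a 3D stack would see the whole object. The real slice profile is
depth-dependent; the Gaussian is not.

**Determinism.** Per-channel accumulation sorts contributions by (sample
index, value) before summation, so channel data are bitwise independent of
the order in which sources are listed.

## Reconstruction

Per-pixel delay-and-sum with linear interpolation between samples;
out-of-window delays contribute nothing, and a pixel reachable by no
element within the record is zeroed with a coverage warning. The angular
weight is cos^q θ (q = 1 by default) inside a 60° acceptance cone — the
actual weighting used clinically is undisclosed beyond "angular weights",
so the cosine (element obliquity factor) is the field-standard choice.
Per-pixel normalization by Σw flattens aperture falloff so that the
depth-amplitude trend in the depth-series experiment is attributable to
fluence and 1/r spreading rather than to element coverage.

PA images are kept bipolar — no envelope, no non-negativity — because the
paired bright/dark lobes are what make a point-like metal target
recognizable against vessels. B-mode display is a separate step: per-column
analytic-signal envelope along depth, normalization to the image maximum,
log compression over a dB dynamic range with additive gain, clipped to
[0, 1]. Because B-mode self-normalizes, *cross-image* amplitude
comparisons (e.g. vertical vs. parallel marker visibility) are made on the
linear envelope (`rf_envelope`) instead.

Multi-angle joint reconstruction poses each view's geometry into the
common frame and beamforms the union of elements as one aperture —
coherent summation in the amplitude domain, not image averaging. Whether
the original system combines views coherently is unstated; coherent
combination is chosen because it is what the shared time base of a rotated
single array permits and it strictly improves the point-spread function.
3D volumes stack independently reconstructed elevational slices.

`locate_peak` refines the |value| argmax with a separable three-point
parabola (offset clipped to ±½ pixel) and breaks exact ties toward
smaller depth, then smaller lateral position. `feature_extent` measures
the bounding box of the 8-connected above-threshold component containing
the peak; a single-pixel feature has extent one pixel spacing.

## Display and fusion

The bipolar colormap maps −s → black, 0 → mid-gray, +s → white with s the
99.9th percentile of |values| (robust to a single hot pixel; a full-max
normalization is one config field away). MIPs zero negative values before
projecting — the negative lobe of every bipolar feature would otherwise
shadow weaker positive structure. Fusion is additive: purple (1,0,1)
weighted by normalized US plus cyan (0,1,1) weighted by normalized |PA|,
clipped; the choice of hues is exactly what makes co-located maxima white.
Exported PNGs carry a burned-in scale bar (default 10 mm).

## Problem sizes and tolerances

Unit tests run on 8–32-element arrays with 256–1024 samples; the
end-to-end contracts use the full 128-element arrays on grids of
0.05–0.1 mm spacing over a few centimeters, chosen so the whole suite
completes in well under a minute of beamforming time while keeping the
point-spread function resolved by ≥3 pixels. The vectorized beamformer is
required to match a literal triple-loop reference to 1e-6 relative (it
agrees to ~1e-14; the bound leaves headroom for platform math libraries).
Localization and B-mode positioning tolerances are one acoustic wavelength
(0.3 mm at 5 MHz), the physical resolution scale, not the pixel scale.

## Known limitations

* No acoustic attenuation, speed-of-sound heterogeneity, or reflection
  artifacts; real in vivo images contain all three.
* The specular echogenicity model uses a fixed probe direction; it is
  not self-consistently recomputed per element or per ring view.
* The elevational Gaussian is a sensitivity profile, not wave physics; 3D
  resolution along y is optimistic near the focus and pessimistic far
  from it.
* Tissue background is statistically stationary speckle plus isolated
  vessels — no fascia planes, no shadowing, no clutter from the chest
  wall, so detection-style conclusions (e.g. recognition rates) cannot be
  read off these phantoms; only orderings and localization accuracy are
  claimed.
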