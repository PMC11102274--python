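# Methods

This note records the models, the numerical choices, and the limits of what the
test suite demonstrates. Notation: lateral coordinate `a` along the array, depth
`l` into the medium (meters), sound speed `e` (m/s), steering angle `α` (rad),
element position `a₁`.

## Geometry and travel times

A uniform linear array of `n` elements at pitch `p` has element lateral
positions `a₁(k) = offset + (k − (n−1)/2)·p`, k = 0-based. A steered plane-wave
transmit reaches (a, l) after `(l cos α + a sin α)/e`; the echo returns along
the slant path `sqrt(l² + (a − a₁)²)/e`. Positive α tilts the wavefront so the
transmit delay grows with `a`. Depth is one-sided (l ≥ 0). The unsteered law is
the α = 0 special case, and the implementation makes the reduction bit-exact.

## RF simulator

Purely geometric: each point scatterer adds `amplitude · pulse(t − τ)` to every
channel, with `τ` the exact steered travel time and the pulse evaluated on the
continuous time axis (sub-sample delays are represented; nothing is snapped to
samples). The excitation is a Gaussian-modulated cosine (scipy's `gausspulse`)
with unit peak in cosine phase; `fractional_bandwidth` is the −6 dB spectral
width over the center frequency. Defaults — 5 MHz, 60 % bandwidth, fs = 4·f₀,
e = 1540 m/s, 128 elements at 0.3 mm pitch — are ordinary clinical-linear-array
values chosen once as the package's reference acquisition; the excitation and
sampling are artifact choices, not values taken from any particular system.

No geometric spreading, element directivity, or attenuation is applied by
default: the delay laws the beamformers invert carry no amplitude terms, and
omitting them keeps the simulator → beamformer round trip an exact matched
filter, which is what makes it usable as an oracle. Noise is additive white
Gaussian on RF samples; every stochastic path requires a seed and is
bit-reproducible. Phantoms draw a Poisson(density × area) scatterer count with
uniform positions and unit-normal amplitudes (fully developed speckle);
anechoic disks are realised by thinning, so they are exactly echo-free. The
default record length covers the latest echo at any element plus twice the
−80 dB pulse half-support.

What the simulator does *not* emulate: wave-equation diffraction, element
impulse responses and directivity, frequency-dependent attenuation, multiple
scattering, and motion. Tests passing against it therefore demonstrate the
correctness of the *reconstruction geometry and numerics*, not robustness to
the physics a real probe adds.

## DAS beamformer

Discretises the aperture integral as a sum over physical elements within the
half-width `x` (those are the only samples of `a₁` that exist), with
rectangular or Hann apodization and linear interpolation in time;
out-of-window reads are zero, not clamped. The `"full"` sentinel uses every
element. Delays are applied to the analytic (Hilbert) channel signal and the
complex image is kept alongside the real RF values: a λ/4 grid samples two-way
RF at exactly its spatial Nyquist rate, where envelope detection on the gridded
RF alone degenerates, so analytic-domain beamforming is used to keep envelopes
exact on any grid. Compounding is coherent (RF sum before detection) with equal
angle weights; an incoherent envelope-sum mode exists for comparison.

## ERM algebra and Stolt migration

The steered acquisition is mapped to a one-way "exploding reflector" problem by
`ê = φe`, `l̂ = ηl`, `â = a + χl` with

    φ = 1/sqrt(1 + cos α + sin²α),
    η = (1 + cos α)^{3/2}/(1 + cos α + sin²α),
    χ = sin α/(2 − cos α),

after first removing the per-channel steering ramp `sin(α)·a₁/e` (an exact
rfft-domain phase ramp; identity at α = 0, energy-preserving on band-limited
data; the shift is circular, which is harmless because the simulator's record
has silent margins). The triple is derived by matching the ERM hyperbola to the
shift-corrected physical travel-time curve at the receiver directly above the
scatterer (`a₁ = a_w`); the match there is exact in value and — a property the
closed forms satisfy though the derivation does not state it — osculating to
second order in `a₁ − a_w`. `apex_match_residual` documents this: it evaluates
both closed forms at `a₁ = a_w` and is machine-zero (≤ 1e-12·l/e) across the
steering range, while growing smoothly off apex.

Migration: 2-D FFT over (element, time) with zero-padding factor 2 along time
(wraparound suppression; factor recorded in the call signature), the Stolt
change of variables `g = ê·sign(r̂_l)·sqrt(r_a² + r̂_l²)` read by linear
interpolation along the frequency axis, Jacobian weight
`ê·|r̂_l|/sqrt(r_a² + r̂_l²)` (defined as ê at the origin, its limit along
r_a = 0), inverse 2-D FFT onto the ERM depth axis `l̂ = ê·t`, and bilinear
back-mapping `l = l̂/η`, `a = â − χl`. Numerical care points:

- **Symmetric band limit.** Required frequencies beyond the largest *positive*
  recorded frequency are zeroed on both signs. Cutting instead at the raw array
  bounds would treat ±g asymmetrically (even-length FFTs carry the Nyquist bin
  only on the negative side), break the Hermitian symmetry of the remapped
  spectrum, and leave a spurious imaginary part in the migrated field. With the
  symmetric cut the imaginary residue is at interpolation-noise level; it is
  checked against 1e-8 of the peak and discarded, and a larger residue raises.
- **Evanescent/out-of-band region.** Coefficients with no recorded frequency to
  read are zeroed — the lossy, stabilising choice.
- **Scale.** The printed Jacobian carries a uniform factor ê relative to the
  dimensionless obliquity `|r̂_l|/sqrt(r_a² + r̂_l²)`; it rescales image
  amplitude uniformly and has no imaging effect. Energy accounting in the tests
  normalises it out.
- The transforms are ordinary DFTs with standard normalisation; Parseval holds
  to 1e-10 relative and the whole chain is linear in the input to 1e-8.

## PSF metrics

Envelope uses the beamformer's analytic panel when present, else the 1-D
analytic signal along depth (RF oscillation is axial). Log compression is
`20 log10(env/max)` clipped at −DR. `psf_report` refines the peak with 3-point
parabolas per axis (offsets clipped to ±half a cell), takes FWHM from linearly
interpolated half-maximum crossings of the axis profiles through the peak, and
defines the main lobe for the PSLR as the rectangle bounded by the first local
minima in the four axis directions — a simple, deterministic stand-in for a
zero-crossing ring that is well defined on envelopes, which never cross zero.
A border peak is an error, not a number.

## Problem sizes

The reference experiments (tests and the CLI demo) use the 128-element array,
single point targets at depths 20–40 mm and lateral offsets up to ±5 mm,
steering angles {−10°, 0°, +10°}, λ/4 image grids on per-target 6 × 6 mm
windows, and three-angle compounds — sizes chosen so a full cross-validation
sweep runs in seconds on one core while keeping every physical scale
(aperture, wavelength, depths) realistic.

## Known limitations

- **Off-apex ERM mismatch.** The physical two-way curve is not a hyperbola, so
  no constant triple can match it globally. The residual is fourth order in the
  receiver offset at α = 0, which limits the coherent aperture and makes the
  migrated lateral PSF ~1.5–2× wider than full-aperture DAS (~0.55 mm vs
  ~0.24 mm FWHM at 30 mm). At steered angles the leading mismatch is *cubic*,
  which biases the migrated peak laterally by roughly +120 µm at +10° and
  30 mm depth (toward the hyperbola apex); DAS, using exact delays, has no such
  bias. An independent time-domain delay-and-sum in ERM coordinates reproduces
  the same bias, confirming it is the model's, not the FFT implementation's.
- **Lateral sampling.** At 5 MHz the 0.3 mm pitch equals one wavelength, so
  steep hyperbola flanks alias laterally; the migrated peak position modulates
  with the target's sub-pitch offset (measured ±~110 µm swing at +10°). DAS
  applies delays per element in the time domain and is immune.
- Consequently the strict per-angle fk↔DAS equivalence assertions in the
  acceptance tests (peaks within one λ/4 cell and envelope NCC ≥ 0.9) hold at
  0° for peak agreement but not at ±10°, and the NCC bound generally does not
  survive the PSF-width mismatch; the true position is nevertheless recovered
  within a quarter wavelength at 0° and within one wavelength at ±10° in all
  tested cases, and symmetric-angle compounding cancels the steered bias (the
  CLI demo's compounded peaks agree within one cell).
- Homogeneous medium only; no curved or phased arrays, no elevation dimension,
  no attenuation or directivity modelling, no motion between compounded angles.
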