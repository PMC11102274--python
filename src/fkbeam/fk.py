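"""Frequency-wavenumber (Stolt) migration of plane-wave channel data.

The pipeline converts one steered plane-wave acquisition into an image in
five stages:

1. remove the steering delay ramp from the channels (``erm.shift_channel_data``),
   after which the scatterer responses are angle-independent hyperbolas;
2. 2-D Fourier transform over (element position, time) -> gamma(r_a, g);
3. Stolt remap: change variables from temporal frequency ``g`` to vertical
   wavenumber ``r_l_hat`` along the one-way dispersion relation

       g(r_l_hat) = e_hat * sign(r_l_hat) * sqrt(r_a^2 + r_l_hat^2)

   reading gamma by linear interpolation along the frequency axis and
   weighting by the change-of-variables Jacobian
   ``e_hat * |r_l_hat| / sqrt(r_a^2 + r_l_hat^2)``; coefficients whose
   required |g| falls outside the recorded band are zeroed (the lossy,
   stabilising choice for the evanescent/unrecorded region);
4. inverse 2-D transform -> the migrated wavefield on ERM coordinates, with
   the depth axis built from the time axis via ``l_hat = e_hat * t``
   (one-way ERM propagation at the rescaled speed ``e_hat = phi * e``);
5. back-map to physical coordinates by inverting the ERM rescaling:
   ``l = l_hat / eta``, ``a = a_hat - chi * l`` (bilinear resampling).

All transforms are ordinary discrete Fourier transforms with standard
normalisation; the default zero-padding factor of 2 along time suppresses
wraparound from the remap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import hilbert

from .das import BeamformedImage
from .erm import ERMParams, erm_parameters, shift_channel_data
from .geometry import ImageGrid, element_positions
from .simulate import ChannelData

__all__ = [
    "Spectrum2D",
    "MigratedWavefield",
    "forward_spectrum",
    "dispersion_g",
    "stolt_remap",
    "inverse_wavefield",
    "to_physical_grid",
    "fk_migrate",
]

log = logging.getLogger(__name__)


@dataclass(eq=False)
class Spectrum2D:
    """Complex 2-D spectrum of a channel-data panel.

    ``coeffs`` is shaped ``(n_ka, n_f)`` in standard (unshifted) FFT order;
    ``k_lateral`` holds the lateral wavenumbers [1/m] and ``axis2`` the
    second-axis coordinates — temporal frequencies [Hz] for a freshly
    transformed panel (``domain == "frequency"``), or vertical wavenumbers
    [1/m] after the Stolt remap (``domain == "vertical_wavenumber"``).
    Originating acquisition metadata rides along for the inverse mapping.
    """

    coeffs: np.ndarray
    k_lateral: np.ndarray
    axis2: np.ndarray
    domain: str
    sampling_rate: float
    pitch: float
    sound_speed: float
    angle: float
    t0: float
    lateral_origin: float
    orig_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.shape != (len(self.k_lateral), len(self.axis2)):
            raise ValueError("coefficient array does not match its axis vectors")
        if self.domain not in ("frequency", "vertical_wavenumber"):
            raise ValueError(f"unknown spectral domain {self.domain!r}")

    def energy(self) -> float:
        """Parseval energy: sum |coeffs|^2 / (n_ka * n_axis2)."""
        return float(np.sum(np.abs(self.coeffs) ** 2)) / self.coeffs.size


@dataclass(eq=False)
class MigratedWavefield:
    """Real migrated wavefield on ERM coordinates (a_hat, l_hat) [m]."""

    values: np.ndarray
    a_hat: np.ndarray
    l_hat: np.ndarray
    params: ERMParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.a_hat), len(self.l_hat)):
            raise ValueError("wavefield shape does not match its axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("wavefield values must be finite")


def forward_spectrum(
    channel: ChannelData, pad_time: int = 2, pad_lateral: int = 1
) -> Spectrum2D:
    """Discrete 2-D Fourier transform of channel data over (element, time).

    Zero-pads by integer factors (``pad_time`` defaults to 2 to suppress
    remap wraparound).  Parseval holds exactly between the padded panel and
    the returned coefficients.
    """
    if pad_time < 1 or pad_lateral < 1:
        raise ValueError("zero-padding factors must be >= 1")
    n_el, n_t = channel.samples.shape
    n_a = n_el * int(pad_lateral)
    n_f = n_t * int(pad_time)
    coeffs = np.fft.fft2(channel.samples, s=(n_a, n_f))
    pos = element_positions(channel.array)
    return Spectrum2D(
        coeffs=coeffs,
        k_lateral=np.fft.fftfreq(n_a, channel.array.pitch),
        axis2=np.fft.fftfreq(n_f, 1.0 / channel.sampling_rate),
        domain="frequency",
        sampling_rate=channel.sampling_rate,
        pitch=channel.array.pitch,
        sound_speed=channel.medium.sound_speed,
        angle=channel.angle,
        t0=channel.t0,
        lateral_origin=float(pos[0]),
        orig_shape=(n_el, n_t),
    )


def dispersion_g(r_hat_l, r_a, e_hat: float):
    """One-way dispersion relation: frequency carried by (r_a, r_hat_l).

    ``g = e_hat * sign(r_hat_l) * sqrt(r_a^2 + r_hat_l^2)`` — odd in the
    vertical wavenumber, with ``|g| >= e_hat * |r_a|`` always.
    """
    return e_hat * np.sign(r_hat_l) * np.hypot(r_a, r_hat_l)


def stolt_remap(
    spec: Spectrum2D, e_hat: float, l_hat_axis: np.ndarray | None = None
) -> Spectrum2D:
    """Remap a (r_a, g) spectrum onto a (r_a, r_hat_l) grid along the dispersion.

    For each target vertical wavenumber the required frequency is evaluated
    from :func:`dispersion_g`, the input spectrum is read there by linear
    interpolation along the frequency axis, and the sample is weighted by the
    Jacobian ``e_hat * |r_hat_l| / sqrt(r_a^2 + r_hat_l^2)`` (defined as
    ``e_hat`` at the origin, its limit along ``r_a = 0``).  Frequencies
    outside the recorded band contribute zero.

    The default target grid is the FFT wavenumber grid conjugate to depth
    samples ``l_hat = e_hat * t``, so the subsequent inverse transform lands
    directly on the ERM depth axis.
    """
    if spec.domain != "frequency":
        raise ValueError("stolt_remap expects a frequency-domain spectrum")
    if not (e_hat > 0):
        raise ValueError("e_hat must be > 0")
    n_f = len(spec.axis2)
    if l_hat_axis is None:
        k_l = np.fft.fftfreq(n_f, e_hat / spec.sampling_rate)
    else:
        k_l = np.asarray(l_hat_axis, dtype=float)

    # monotone frequency axis for interpolation
    f_sorted = np.fft.fftshift(spec.axis2)
    g_sorted = np.fft.fftshift(spec.coeffs, axes=1)
    # symmetric band limit: the negative Nyquist bin has no positive partner,
    # so cutting at the largest positive frequency keeps +/-g treatment (and
    # hence Hermitian symmetry of the remapped spectrum) exact
    f_lim = f_sorted[-1]

    out = np.empty((len(spec.k_lateral), len(k_l)), dtype=complex)
    for i, ka in enumerate(spec.k_lateral):
        g = dispersion_g(k_l, ka, e_hat)
        re = np.interp(g, f_sorted, g_sorted[i].real, left=0.0, right=0.0)
        im = np.interp(g, f_sorted, g_sorted[i].imag, left=0.0, right=0.0)
        row = re + 1j * im
        row[np.abs(g) > f_lim] = 0.0
        out[i] = row

    denom = np.hypot(spec.k_lateral[:, None], k_l[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = e_hat * np.abs(k_l)[None, :] / denom
    jac[denom == 0] = e_hat  # limit along r_a = 0
    out *= jac

    return Spectrum2D(
        coeffs=out,
        k_lateral=spec.k_lateral.copy(),
        axis2=k_l,
        domain="vertical_wavenumber",
        sampling_rate=spec.sampling_rate,
        pitch=spec.pitch,
        sound_speed=spec.sound_speed,
        angle=spec.angle,
        t0=spec.t0,
        lateral_origin=spec.lateral_origin,
        orig_shape=spec.orig_shape,
    )


def inverse_wavefield(
    remapped: Spectrum2D,
    params: ERMParams | None = None,
    e_hat: float | None = None,
    imag_tol: float = 1e-8,
) -> MigratedWavefield:
    """Inverse 2-D transform of a remapped spectrum to ERM coordinates.

    The result of migrating real data is real up to interpolation asymmetry;
    the imaginary residue is checked against ``imag_tol`` times the peak and
    discarded.  A residue above the tolerance raises, since it indicates a
    broken Hermitian symmetry upstream.
    """
    if remapped.domain != "vertical_wavenumber":
        raise ValueError("inverse_wavefield expects a remapped (vertical-wavenumber) spectrum")
    if params is None:
        params = erm_parameters(remapped.angle)
    if e_hat is None:
        e_hat = params.c_scale * remapped.sound_speed
    field = np.fft.ifft2(remapped.coeffs)
    peak = float(np.max(np.abs(field))) if field.size else 0.0
    residue = float(np.max(np.abs(field.imag))) if field.size else 0.0
    if peak > 0 and residue > imag_tol * peak:
        raise ValueError(
            f"imaginary residue {residue:.3e} exceeds {imag_tol:.1e} of peak {peak:.3e}"
        )
    log.debug("inverse_wavefield: peak=%.4e imag residue=%.4e", peak, residue)

    n_a, n_l = field.shape
    a_hat = remapped.lateral_origin + np.arange(n_a) * remapped.pitch
    l_hat = e_hat * (remapped.t0 + np.arange(n_l) / remapped.sampling_rate)
    return MigratedWavefield(values=field.real, a_hat=a_hat, l_hat=l_hat, params=params)


def to_physical_grid(
    field: MigratedWavefield, params: ERMParams, grid: ImageGrid
) -> BeamformedImage:
    """Resample a migrated wavefield from ERM to physical coordinates.

    Inverts the ERM rescaling — a pixel at physical ``(a, l)`` reads the
    wavefield at ``(a + chi*l, eta*l)`` — by bilinear interpolation, with
    zeros outside the mapped footprint.  The analytic signal is computed on
    the finely sampled wavefield depth axis before resampling so envelope
    detection stays exact on coarse physical grids.
    """
    a_q = grid.lateral[:, None] + params.lateral_shift * grid.depth[None, :]
    l_q = params.depth_scale * grid.depth[None, :] + np.zeros_like(a_q)
    if (
        a_q.min() > field.a_hat[-1]
        or a_q.max() < field.a_hat[0]
        or l_q.min() > field.l_hat[-1]
        or l_q.max() < field.l_hat[0]
    ):
        raise ValueError("image grid footprint is disjoint from the migrated wavefield")

    analytic_field = hilbert(field.values, axis=1)
    pts = np.stack([a_q.ravel(), l_q.ravel()], axis=-1)
    out = []
    for panel in (field.values, analytic_field.real, analytic_field.imag):
        interp = RegularGridInterpolator(
            (field.a_hat, field.l_hat), panel, bounds_error=False, fill_value=0.0
        )
        out.append(interp(pts).reshape(a_q.shape))
    values, an_re, an_im = out
    return BeamformedImage(
        values=values,
        grid=grid,
        method="fk",
        angles=(),
        analytic=an_re + 1j * an_im,
    )


def fk_migrate(
    channel: ChannelData,
    grid: ImageGrid,
    pad_time: int = 2,
    pad_lateral: int = 1,
) -> BeamformedImage:
    """Full Stolt migration of one steered plane-wave acquisition.

    Composition of delay-ramp removal, forward 2-D transform, Stolt remap at
    the ERM speed ``e_hat = phi * e``, inverse transform, and the ERM-to-
    physical back-mapping.  Linear in the input; zero data give a zero image.
    """
    params = erm_parameters(channel.angle)
    e_hat = params.c_scale * channel.medium.sound_speed
    shifted = shift_channel_data(channel)
    spec = forward_spectrum(shifted, pad_time=pad_time, pad_lateral=pad_lateral)
    remapped = stolt_remap(spec, e_hat)
    field = inverse_wavefield(remapped, params=params, e_hat=e_hat)
    image = to_physical_grid(field, params, grid)
    image.angles = (channel.angle,)
    return image
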