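"""Explosive-reflection-model (ERM) algebra for steered plane waves.

The ERM is the fiction that scatterers "explode" at time zero and radiate
one-way, which turns the two-way plane-wave acquisition into an equivalent
one-way problem — the prerequisite for Stolt f-k migration.  For a steered
transmit at angle ``alpha`` the equivalence is obtained by rescaling speed,
depth, and lateral position with a constant triple ``(phi, eta, chi)``::

    e_hat  = phi * e
    l_hat  = eta * l_w
    a_hat  = a_w + chi * l_w

    phi = 1 / sqrt(1 + cos(alpha) + sin(alpha)^2)
    eta = (1 + cos(alpha))^(3/2) / (1 + cos(alpha) + sin(alpha)^2)
    chi = sin(alpha) / (2 - cos(alpha))

At ``alpha = 0`` this reduces to the classical ``e_hat = e/sqrt(2)``,
``l_hat = sqrt(2) l_w`` one-way equivalence.  The triple is derived by
matching the ERM hyperbola to the (shift-corrected) physical travel-time
hyperbola at the receiver directly above the scatterer, ``a1 = a_w``; the
match there is exact in value and — a property the derivation does not state
but which the closed forms satisfy — osculating to second order in
``a1 - a_w``, which is why the migrated energy focuses at the mapped
position.

Before migration the per-channel linear delay ``sin(alpha) * a1 / e``
introduced by the steered transmit must be removed (the scatterer responses
then "move down as a whole" onto angle-independent hyperbolas); that shift is
implemented here as an exact phase ramp in the temporal frequency domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import element_positions
from .simulate import ChannelData

__all__ = [
    "ERMParams",
    "erm_parameters",
    "erm_travel_time",
    "shifted_physical_time",
    "shift_channel_data",
    "apex_match_residual",
]


@dataclass(frozen=True)
class ERMParams:
    """The (phi, eta, chi) triple mapping a steered acquisition to its ERM twin.

    ``c_scale`` (phi) scales the sound speed, ``depth_scale`` (eta) the
    scatterer depth, and ``lateral_shift`` (chi) shears the lateral position
    by ``chi * l_w``.
    """

    c_scale: float
    depth_scale: float
    lateral_shift: float

    def __post_init__(self) -> None:
        if not (self.c_scale > 0):
            raise ValueError("c_scale must be > 0")
        if not (self.depth_scale > 0):
            raise ValueError("depth_scale must be > 0")


def erm_parameters(angle: float) -> ERMParams:
    """Closed-form ERM constants for a steering angle [rad].

    Continuous in the angle; at 0 returns ``(sqrt(2)/2, sqrt(2), 0)``; eta is
    even and chi odd under a sign flip of the angle.
    """
    if not abs(angle) < np.pi / 2:
        raise ValueError(f"|angle| must be < pi/2, got {angle}")
    c, s = np.cos(angle), np.sin(angle)
    denom = 1.0 + c + s * s
    return ERMParams(
        c_scale=1.0 / np.sqrt(denom),
        depth_scale=(1.0 + c) ** 1.5 / denom,
        lateral_shift=s / (2.0 - c),
    )


def erm_travel_time(params: ERMParams, e: float, a1, a_w, l_w):
    """One-way ERM echo time from the mapped scatterer to element ``a1``.

    ``beta_hat = sqrt((a_w + chi*l_w - a1)^2 + eta^2 * l_w^2) / (phi * e)``.
    At the angle-0 parameters and ``a1 = a_w`` this equals ``2 l_w / e``, the
    physical two-way apex time.
    """
    if np.any(np.asarray(l_w) < 0):
        raise ValueError("l_w must be >= 0")
    num = np.hypot(
        np.asarray(a_w) + params.lateral_shift * np.asarray(l_w) - np.asarray(a1),
        params.depth_scale * np.asarray(l_w),
    )
    return num / (params.c_scale * e)


def shifted_physical_time(angle: float, e: float, a1, a_w, l_w):
    """Physical steered travel time after removing the ``sin(alpha)*a1/e`` ramp.

    ``beta = (sin(alpha)*(a_w - a1) + cos(alpha)*l_w + sqrt(l_w^2 + (a_w - a1)^2)) / e``;
    reduces to the unsteered two-way law at angle 0.
    """
    if np.any(np.asarray(l_w) < 0):
        raise ValueError("l_w must be >= 0")
    d = np.subtract(a_w, a1)
    return (np.sin(angle) * d + np.cos(angle) * np.asarray(l_w) + np.hypot(l_w, d)) / e


def shift_channel_data(channel: ChannelData) -> ChannelData:
    """Remove the steering delay ramp from recorded channel data.

    The channel recorded at lateral position ``a1`` is advanced in time by
    ``sin(angle) * a1 / e`` (a delay for negative products), applied as an
    exact linear phase ramp in the temporal frequency domain so sub-sample
    shifts are represented without interpolation loss.  At angle 0 the
    operation is the identity to machine precision.  Being a pure phase
    operation it preserves signal energy on band-limited data.
    """
    shift = np.sin(channel.angle) * element_positions(channel.array) / channel.medium.sound_speed
    if not np.any(shift):
        return replace(channel, samples=channel.samples.copy())
    n = channel.n_samples
    spec = np.fft.rfft(channel.samples, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / channel.sampling_rate)
    # y(t) = x(t + shift)  <=>  Y(f) = X(f) * exp(+2i pi f shift)
    spec *= np.exp(2j * np.pi * f[None, :] * shift[:, None])
    out = np.fft.irfft(spec, n=n, axis=1)
    return replace(channel, samples=out)


def apex_match_residual(angle: float, e: float, a_w, l_w):
    """Absolute mismatch between the ERM and shifted physical times at the apex.

    Both hyperbolas are evaluated at the receiver directly above the true
    scatterer lateral position, ``a1 = a_w`` — the matching point of the
    parameter derivation, where the residual is zero to machine precision for
    every steering angle.  Away from that receiver the two curves separate
    smoothly (the matching is exact only at the apex).
    """
    params = erm_parameters(angle)
    t_erm = erm_travel_time(params, e, a_w, a_w, l_w)
    t_phys = shifted_physical_time(angle, e, a_w, a_w, l_w)
    return np.abs(t_erm - t_phys)
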