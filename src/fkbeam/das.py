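"""Delay-and-sum (DAS) image formation and coherent multi-angle compounding.

For every pixel ``(a, l)`` the beamformer reads each receive channel at that
pixel's steered two-way travel time and sums across the aperture:

    w(a, l) = sum over elements with |a1 - a| <= x of
              apod(a1 - a) * channel_k(tau(angle, a1, a, l))

with linear interpolation for fractional-sample reads and zeros outside the
recorded window.  The continuous aperture integral is discretised as a sum
over physical elements because those are the only samples of ``a1`` that
exist.

Delays are applied to the analytic (Hilbert-transformed) channel signal; the
stored image ``values`` are the real RF part, and the complex panel is kept
alongside so that envelope detection stays exact on coarse grids (an image
grid at a quarter wavelength samples two-way RF at its spatial Nyquist rate,
where envelope detection on the gridded RF alone degenerates).

Compounding sums the per-angle RF images coherently before envelope
detection, which is what turns the multi-angle scheme into a synthetic
transmit focus; an incoherent (envelope-sum) mode exists for comparison.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .geometry import ImageGrid, element_positions, travel_time_steered
from .simulate import ChannelData

__all__ = ["ApertureSpec", "BeamformedImage", "das_beamform", "coherent_compound"]

log = logging.getLogger(__name__)

#: sentinel accepted for ApertureSpec.half_width meaning "use all elements"
FULL = math.inf


@dataclass(frozen=True)
class ApertureSpec:
    """Receive aperture: half-width ``x`` [m] about each pixel, plus apodization.

    ``half_width`` may be the string ``"full"`` or ``math.inf`` to use every
    element for every pixel.  Apodization is ``"rectangular"`` or ``"hann"``.
    """

    half_width: float = FULL
    apodization: str = "rectangular"

    def __post_init__(self) -> None:
        hw = self.half_width
        if isinstance(hw, str):
            if hw != "full":
                raise ValueError(f"unknown aperture sentinel {hw!r}")
            hw = FULL
        if not (hw > 0):
            raise ValueError("aperture half-width must be > 0")
        object.__setattr__(self, "half_width", float(hw))
        if self.apodization not in ("rectangular", "hann"):
            raise ValueError(f"unknown apodization {self.apodization!r}")

    @property
    def is_full(self) -> bool:
        return math.isinf(self.half_width)


@dataclass(eq=False)
class BeamformedImage:
    """Beamformed RF image ``w(a, l)`` on an :class:`ImageGrid`.

    ``values`` is real RF shaped ``(n_lateral, n_depth)``; ``analytic`` is the
    matching complex (analytic-signal) panel when the forming method produced
    one, used for exact envelope detection.
    """

    values: np.ndarray
    grid: ImageGrid
    method: str
    angles: tuple[float, ...]
    analytic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.angles = tuple(float(a) for a in self.angles)
        if self.analytic is not None:
            self.analytic = np.asarray(self.analytic, dtype=complex)
            if self.analytic.shape != self.values.shape:
                raise ValueError("analytic panel shape must match values")


def das_beamform(
    channel: ChannelData, grid: ImageGrid, aperture: ApertureSpec = ApertureSpec()
) -> BeamformedImage:
    """Delay-and-sum one plane-wave acquisition onto an image grid.

    Linear in the channel samples; out-of-window reads contribute zero; a
    pixel whose aperture contains no element is left at zero (with a logged
    warning).
    """
    pos = element_positions(channel.array)
    e = channel.medium.sound_speed
    t = channel.time_axis
    analytic = hilbert(channel.samples, axis=1)

    a = grid.lateral[:, None]
    l = grid.depth[None, :]
    acc = np.zeros(grid.shape, dtype=complex)

    if not aperture.is_full:
        within = np.abs(pos[None, :] - grid.lateral[:, None]) <= aperture.half_width
        empty = ~within.any(axis=1)
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} lateral grid positions have an empty aperture "
                f"(half-width {aperture.half_width:.3e} m); their pixels stay 0",
                stacklevel=2,
            )

    for k, a1 in enumerate(pos):
        dist = np.abs(a1 - a)  # (n_lat, 1)
        if aperture.is_full:
            w = np.ones_like(dist)
        else:
            w = (dist <= aperture.half_width).astype(float)
            if not w.any():
                continue
        if aperture.apodization == "hann":
            x = aperture.half_width
            if aperture.is_full:
                # taper over the farthest in-use element distance per pixel
                x = np.maximum(np.abs(pos[0] - a), np.abs(pos[-1] - a)) + channel.array.pitch
            w = w * (0.5 + 0.5 * np.cos(np.pi * np.minimum(dist / x, 1.0)))
        tau = travel_time_steered(channel.angle, a1, a, l, e)
        re = np.interp(tau, t, analytic[k].real, left=0.0, right=0.0)
        im = np.interp(tau, t, analytic[k].imag, left=0.0, right=0.0)
        acc += w * (re + 1j * im)

    log.debug("das_beamform: angle=%.4f rad, image energy=%.6e",
              channel.angle, float(np.sum(acc.real**2)))
    return BeamformedImage(
        values=acc.real,
        grid=grid,
        method="das",
        angles=(channel.angle,),
        analytic=acc,
    )


def coherent_compound(images, incoherent: bool = False) -> BeamformedImage:
    """Sum per-angle beamformed images into one compound image.

    Coherent mode (default) sums RF (and analytic) panels elementwise before
    any envelope detection; incoherent mode sums envelopes instead, which
    smooths speckle but forfeits the synthetic-focus resolution gain.
    Contributing-angle metadata is the union of the inputs'.
    """
    images = list(images)
    if not images:
        raise ValueError("cannot compound an empty image list")
    base = images[0]
    for img in images[1:]:
        if not base.grid.same_axes(img.grid):
            raise ValueError("all images must share one grid")

    angles: list[float] = []
    for img in images:
        for ang in img.angles:
            if ang not in angles:
                angles.append(ang)

    if incoherent:
        env = np.zeros(base.grid.shape)
        for img in images:
            env += np.abs(img.analytic) if img.analytic is not None else np.abs(
                hilbert(img.values, axis=1)
            )
        return BeamformedImage(env, base.grid, "das-incoherent-compound", tuple(angles))

    values = sum(img.values for img in images)
    if all(img.analytic is not None for img in images):
        analytic = sum(img.analytic for img in images)
    else:
        analytic = None
    return BeamformedImage(values, base.grid, base.method + "-compound", tuple(angles), analytic)
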