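"""Synthetic multi-channel RF data for steered plane-wave acquisitions.

The simulator is deliberately geometric: each point scatterer contributes a
replica of the excitation pulse to every receive channel, centered at the
exact (continuous-time) steered two-way travel time, with optional additive
white Gaussian noise.  There is no wave-equation solve, no element impulse
response, and — by default — no geometric-spreading or directivity weighting,
because the delay laws the beamformers invert carry no amplitude terms.  This
keeps the simulator → beamformer round trip an exact matched-filter problem,
which is what makes it usable as an oracle.

Sub-sample delays are represented exactly: the pulse is evaluated on the
continuous time axis at ``t - tau`` rather than snapped to the nearest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gausspulse

from .geometry import (
    LinearArray,
    Medium,
    PlaneWaveTransmit,
    Pulse,
    element_positions,
    travel_time_steered,
)

__all__ = [
    "Scatterer",
    "ChannelData",
    "PhantomSpec",
    "gaussian_pulse",
    "pulse_cutoff",
    "simulate_channel_data",
    "make_phantom",
]


@dataclass(frozen=True)
class Scatterer:
    """A point reflector at lateral ``a_w``, depth ``l_w`` [m] with a real amplitude."""

    a_w: float
    l_w: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.l_w < 0:
            raise ValueError(f"scatterer depth must be >= 0, got {self.l_w}")


@dataclass(eq=False)
class ChannelData:
    """Per-element RF traces for one plane-wave transmit.

    ``samples`` is shaped ``(n_elements, n_samples)``; row ``k`` is the trace
    recorded by element ``k`` (0-based, lateral position from the array
    geometry).  ``t0`` is the time of sample 0 relative to the transmit.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    angle: float
    array: LinearArray
    medium: Medium

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] == 0:
            raise ValueError("samples must be a 2-D (n_elements, n_samples) array")
        if self.samples.shape[0] != self.array.n_elements:
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but the array has "
                f"{self.array.n_elements} elements"
            )
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def energy(self) -> float:
        return float(np.sum(self.samples**2))


@dataclass(frozen=True)
class PhantomSpec:
    """Speckle/anechoic phantom description for :func:`make_phantom`.

    Scatterer count is Poisson with mean ``density * area`` (fully developed
    speckle); positions are uniform over the box; scatterers falling inside an
    anechoic disk ``(center_a, center_l, radius)`` are removed, which is how a
    cyst target is realised.  ``amplitude`` selects the amplitude law:
    ``"normal"`` (unit normal, the speckle default) or ``"unit"``.
    """

    lateral_min: float
    lateral_max: float
    depth_min: float
    depth_max: float
    density: float
    amplitude: str = "normal"
    disks: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lateral_max > self.lateral_min and self.depth_max > self.depth_min):
            raise ValueError("phantom bounds must be nonempty")
        if self.depth_min < 0:
            raise ValueError("phantom depths must be >= 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.amplitude not in ("normal", "unit"):
            raise ValueError(f"unknown amplitude law {self.amplitude!r}")
        for ca, cl, r in self.disks:
            if not (
                self.lateral_min <= ca <= self.lateral_max
                and self.depth_min <= cl <= self.depth_max
            ):
                raise ValueError("anechoic disk center must lie inside the bounds")
            if r <= 0:
                raise ValueError("anechoic disk radius must be > 0")

    @property
    def area(self) -> float:
        return (self.lateral_max - self.lateral_min) * (self.depth_max - self.depth_min)


def gaussian_pulse(pulse: Pulse, t) -> np.ndarray:
    """Gaussian-modulated cosine excitation evaluated at times ``t`` [s].

    Unit peak at ``t = 0`` in cosine phase; the -6 dB spectral width equals
    ``fractional_bandwidth * center_frequency``.
    """
    return gausspulse(
        np.asarray(t, dtype=float),
        fc=pulse.center_frequency,
        bw=pulse.fractional_bandwidth,
        bwr=-6,
    )


def pulse_cutoff(pulse: Pulse, tpr: float = -80.0) -> float:
    """Half-support of the pulse [s]: time where the envelope falls to ``tpr`` dB."""
    return float(
        gausspulse("cutoff", fc=pulse.center_frequency, bw=pulse.fractional_bandwidth,
                   bwr=-6, tpr=tpr)
    )


def default_duration(
    scatterers, array: LinearArray, medium: Medium, tx: PlaneWaveTransmit, pulse: Pulse
) -> float:
    """Record length covering the latest echo at any element plus pulse support."""
    if not scatterers:
        raise ValueError("cannot infer a duration from an empty scatterer list; pass duration=")
    pos = element_positions(array)
    latest = max(
        float(np.max(travel_time_steered(tx.angle, pos, s.a_w, s.l_w, medium.sound_speed)))
        for s in scatterers
    )
    return latest + 2.0 * pulse_cutoff(pulse)


def simulate_channel_data(
    scatterers,
    array: LinearArray,
    medium: Medium,
    tx: PlaneWaveTransmit,
    pulse: Pulse,
    duration: float | None = None,
    noise_std: float = 0.0,
    rng_seed: int = 0,
) -> ChannelData:
    """Simulate one steered plane-wave acquisition.

    Each receive channel ``k`` records, on the continuous time axis,

        sum over scatterers of  amplitude * pulse(t - tau_k)

    with ``tau_k`` the exact steered two-way travel time from the transmit
    wavefront via the scatterer to element ``k``, plus white Gaussian noise of
    standard deviation ``noise_std``.  Noiseless output is deterministic and
    exactly linear (superposable) in the scatterer list.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    scatterers = list(scatterers)
    if duration is None:
        duration = default_duration(scatterers, array, medium, tx, pulse)
    fs = pulse.sampling_rate
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    t0 = 0.0
    samples = np.zeros((array.n_elements, n))
    pos = element_positions(array)
    tcut = pulse_cutoff(pulse)
    half = int(np.ceil(tcut * fs)) + 1
    width = 2 * half + 1
    col = np.arange(width)

    latest = -np.inf
    for s in scatterers:
        tau = travel_time_steered(tx.angle, pos, s.a_w, s.l_w, medium.sound_speed)
        latest = max(latest, float(np.max(tau)) + tcut)
        if s.amplitude == 0.0:
            continue
        center = np.round((tau - t0) * fs).astype(int)
        idx = center[:, None] + (col[None, :] - half)  # (n_el, width)
        tt = t0 + idx / fs - tau[:, None]
        vals = s.amplitude * gaussian_pulse(pulse, tt)
        inside = (idx >= 0) & (idx < n)
        rows = np.broadcast_to(np.arange(array.n_elements)[:, None], idx.shape)
        np.add.at(samples, (rows[inside], idx[inside]), vals[inside])

    if scatterers and latest > t0 + duration:
        warnings.warn(
            f"duration {duration:.3e} s truncates the latest echo at {latest:.3e} s",
            stacklevel=2,
        )
    if noise_std > 0:
        rng = np.random.default_rng(rng_seed)
        samples += noise_std * rng.standard_normal(samples.shape)

    return ChannelData(
        samples=samples,
        sampling_rate=fs,
        t0=t0,
        angle=tx.angle,
        array=array,
        medium=medium,
    )


def make_phantom(spec: PhantomSpec) -> list[Scatterer]:
    """Draw a seeded random scatterer field from a :class:`PhantomSpec`.

    The count is Poisson(density * area); scatterers landing inside an
    anechoic disk are removed (Poisson thinning), so the disks are exactly
    echo-free.  Identical seeds give identical lists.
    """
    rng = np.random.default_rng(spec.rng_seed)
    count = rng.poisson(spec.density * spec.area)
    a = rng.uniform(spec.lateral_min, spec.lateral_max, count)
    l = rng.uniform(spec.depth_min, spec.depth_max, count)
    keep = np.ones(count, dtype=bool)
    for ca, cl, r in spec.disks:
        keep &= (a - ca) ** 2 + (l - cl) ** 2 > r**2
    a, l = a[keep], l[keep]
    if spec.amplitude == "normal":
        amps = rng.standard_normal(a.size)
    else:
        amps = np.ones(a.size)
    return [Scatterer(float(ai), float(li), float(wi)) for ai, li, wi in zip(a, l, amps)]
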