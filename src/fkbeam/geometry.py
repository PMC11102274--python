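"""Transducer geometry, acquisition primitives, and plane-wave travel-time laws.

Coordinates follow the usual linear-array convention: the lateral axis ``a``
runs along the transducer face, the depth axis ``l`` points into the medium,
both in meters.  Depth is one-sided (``l >= 0``), element indices are 0-based,
and a positive steering angle tilts the transmitted wavefront so that its
arrival delay grows with ``a``.

The two travel-time laws here are the whole geometric content of plane-wave
delay-and-sum imaging:

* unsteered (0-degree) transmit: the wavefront reaches depth ``l`` after
  ``l/e`` and the echo returns to element ``a1`` along the slant path, giving
  ``tau = (l + sqrt(l^2 + (a - a1)^2)) / e``;
* steered transmit at angle ``alpha``: the plane-wave transmit leg becomes
  ``(l cos(alpha) + a sin(alpha)) / e`` while the receive leg is unchanged.

Both the RF simulator and the DAS beamformer call these same functions, so a
matched-filter round trip through the two is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinearArray",
    "Medium",
    "PlaneWaveTransmit",
    "ImageGrid",
    "Pulse",
    "element_positions",
    "travel_time_unsteered",
    "travel_time_steered",
]


@dataclass(frozen=True)
class LinearArray:
    """Uniform linear transducer array.

    Parameters
    ----------
    n_elements : int
        Number of elements (channels); a clinical probe is typically 128.
    pitch : float
        Center-to-center element spacing [m].
    center_offset : float, optional
        Lateral coordinate of the array center [m]; defaults to 0 so the
        aperture is symmetric about the lateral origin.
    """

    n_elements: int
    pitch: float
    center_offset: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n_elements) != self.n_elements or self.n_elements < 1:
            raise ValueError(f"n_elements must be a positive integer, got {self.n_elements}")
        if not (self.pitch > 0):
            raise ValueError(f"pitch must be > 0, got {self.pitch}")

    @property
    def aperture(self) -> float:
        """Full aperture span (n_elements - 1) * pitch [m]."""
        return (self.n_elements - 1) * self.pitch


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium with a single sound speed [m/s]."""

    sound_speed: float

    def __post_init__(self) -> None:
        if not (self.sound_speed > 0):
            raise ValueError(f"sound_speed must be > 0, got {self.sound_speed}")


@dataclass(frozen=True)
class PlaneWaveTransmit:
    """One unfocused plane-wave transmit, described by its steering angle [rad]."""

    angle: float

    def __post_init__(self) -> None:
        if not abs(self.angle) < np.pi / 2:
            raise ValueError(f"|angle| must be < pi/2, got {self.angle}")


@dataclass(frozen=True, eq=False)
class ImageGrid:
    """Rectilinear imaging grid: lateral coordinates ``a`` and depths ``l`` [m].

    Both axes must be strictly increasing and all depths non-negative.
    """

    lateral: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lateral, dtype=float)
        dep = np.asarray(self.depth, dtype=float)
        if lat.ndim != 1 or dep.ndim != 1 or lat.size == 0 or dep.size == 0:
            raise ValueError("grid axes must be nonempty 1-D sequences")
        if np.any(np.diff(lat) <= 0) or np.any(np.diff(dep) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if dep[0] < 0:
            raise ValueError("all depths must be >= 0")
        object.__setattr__(self, "lateral", lat)
        object.__setattr__(self, "depth", dep)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lateral.size, self.depth.size)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (lateral[:, None], depth[None, :]) coordinate arrays."""
        return self.lateral[:, None], self.depth[None, :]

    def same_axes(self, other: "ImageGrid") -> bool:
        return (
            self.lateral.shape == other.lateral.shape
            and self.depth.shape == other.depth.shape
            and np.array_equal(self.lateral, other.lateral)
            and np.array_equal(self.depth, other.depth)
        )

    @classmethod
    def regular(
        cls,
        lateral_min: float,
        lateral_max: float,
        depth_min: float,
        depth_max: float,
        spacing: float,
    ) -> "ImageGrid":
        """Build a grid with equal lateral/axial spacing covering the box."""
        n_a = int(np.floor((lateral_max - lateral_min) / spacing)) + 1
        n_l = int(np.floor((depth_max - depth_min) / spacing)) + 1
        return cls(
            lateral_min + spacing * np.arange(n_a),
            depth_min + spacing * np.arange(n_l),
        )


@dataclass(frozen=True)
class Pulse:
    """Gaussian-modulated cosine excitation.

    ``fractional_bandwidth`` is the -6 dB spectral width divided by the center
    frequency; ``sampling_rate`` must oversample the carrier at least 4x.
    """

    center_frequency: float
    fractional_bandwidth: float = 0.6
    sampling_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.center_frequency > 0):
            raise ValueError("center_frequency must be > 0")
        if not (0 < self.fractional_bandwidth < 2):
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        fs = self.sampling_rate or 4.0 * self.center_frequency
        if fs < 4.0 * self.center_frequency:
            raise ValueError("sampling_rate must be >= 4 * center_frequency")
        object.__setattr__(self, "sampling_rate", float(fs))


def element_positions(array: LinearArray) -> np.ndarray:
    """Lateral coordinates of all elements [m], symmetric about the center."""
    k = np.arange(array.n_elements)
    return array.center_offset + (k - (array.n_elements - 1) / 2.0) * array.pitch


def _check_geometry(l, e) -> None:
    if np.any(np.asarray(l) < 0):
        raise ValueError("depth l must be >= 0")
    if not (e > 0):
        raise ValueError("sound speed e must be > 0")


def travel_time_unsteered(a1, a, l, e: float):
    """Two-way echo time for a 0-degree plane wave.

    ``tau = (l + sqrt(l^2 + (a - a1)^2)) / e`` — the wavefront reaches the
    pixel/scatterer at ``(a, l)`` after ``l/e``, and the backscattered echo
    travels the slant path to the element at lateral position ``a1``.
    Broadcasts over array inputs.
    """
    _check_geometry(l, e)
    return (np.asarray(l) + np.hypot(l, np.subtract(a, a1))) / e


def travel_time_steered(angle: float, a1, a, l, e: float):
    """Two-way echo time for a plane wave steered by ``angle`` [rad].

    Transmit leg ``(l cos(angle) + a sin(angle)) / e`` plus the same receive
    leg as the unsteered law; reduces to :func:`travel_time_unsteered` exactly
    at ``angle = 0``.
    """
    _check_geometry(l, e)
    # single division keeps the angle-0 case bit-identical to the unsteered law
    tx = np.asarray(l) * np.cos(angle) + np.asarray(a) * np.sin(angle)
    return (tx + np.hypot(l, np.subtract(a, a1))) / e
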