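"""Envelope detection, B-mode conversion, and point-spread-function metrics.

These are the quantitative test surface for both beamformers: envelope via
the analytic signal along the depth axis (RF oscillation is axial), log
compression to a fixed dynamic range, and PSF statistics (peak localisation,
lateral/axial FWHM, peak-to-sidelobe ratio) with sub-cell parabolic peak
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .das import BeamformedImage
from .geometry import ImageGrid

__all__ = [
    "PSFReport",
    "envelope_image",
    "log_compress",
    "psf_report",
    "contrast_ratio",
]


class BorderPeakError(ValueError):
    """The image peak sits on the border, so PSF metrics are undefined."""


@dataclass(frozen=True)
class PSFReport:
    """Point-spread-function summary for a single dominant peak.

    Positions and widths in meters; PSLR in dB (>= 0, peak over largest
    sidelobe outside the main lobe).
    """

    peak_lateral: float
    peak_depth: float
    localization_error: float
    fwhm_lateral: float
    fwhm_axial: float
    pslr_db: float

    def to_dict(self) -> dict:
        return {
            "peak_lateral_m": self.peak_lateral,
            "peak_depth_m": self.peak_depth,
            "localization_error_m": self.localization_error,
            "fwhm_lateral_m": self.fwhm_lateral,
            "fwhm_axial_m": self.fwhm_axial,
            "pslr_db": self.pslr_db,
        }


def envelope_image(img: BeamformedImage) -> np.ndarray:
    """Pointwise nonnegative envelope of a beamformed RF image.

    Uses the image's analytic panel when the beamformer recorded one
    (exact regardless of grid spacing); otherwise takes the magnitude of the
    1-D analytic signal along the depth axis.
    """
    if img.analytic is not None:
        return np.abs(img.analytic)
    return np.abs(hilbert(img.values, axis=1))


def log_compress(env: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """B-mode conversion: ``20 log10(env / max)`` clipped below at ``-DR`` dB."""
    if not (dynamic_range_db > 0):
        raise ValueError("dynamic_range_db must be > 0")
    env = np.asarray(env, dtype=float)
    peak = env.max() if env.size else 0.0
    if not (peak > 0):
        raise ValueError("cannot log-compress an all-zero envelope")
    floor = peak * 10.0 ** (-dynamic_range_db / 20.0)
    return 20.0 * np.log10(np.maximum(env / peak, floor / peak))


def _parabolic_offset(ym1: float, y0: float, yp1: float) -> tuple[float, float]:
    """Vertex offset (in cells, clipped to [-0.5, 0.5]) and value of a 3-point parabola."""
    denom = ym1 - 2.0 * y0 + yp1
    if denom == 0:
        return 0.0, y0
    d = 0.5 * (ym1 - yp1) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, y0 - 0.25 * (ym1 - yp1) * d


def _half_crossing(profile: np.ndarray, coords: np.ndarray, i_peak: int, half: float, step: int):
    """Coordinate where the profile first falls through ``half`` walking from the peak."""
    i = i_peak
    while 0 <= i + step < len(profile):
        j = i + step
        if profile[j] < half:
            # linear interpolation between samples i and j
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return coords[i] + frac * (coords[j] - coords[i])
        i = j
    return None


def _first_local_min(profile: np.ndarray, i_peak: int, step: int) -> int:
    """Index of the first local minimum walking from the peak; end index if monotone."""
    i = i_peak
    while 0 <= i + step < len(profile):
        if profile[i + step] > profile[i]:
            return i
        i += step
    return i


def psf_report(env: np.ndarray, grid: ImageGrid, true_position: tuple[float, float]) -> PSFReport:
    """Measure a point-spread function from an envelope image.

    The peak is located with 3-point parabolic sub-cell refinement along each
    axis; FWHM comes from linear interpolation of the half-maximum crossings
    of the axis profiles through the peak; PSLR compares the peak against the
    largest envelope value outside the main-lobe support (the rectangle
    bounded by the first local minima in the four axis directions).
    """
    env = np.asarray(env, dtype=float)
    if env.shape != grid.shape:
        raise ValueError("envelope shape does not match the grid")
    i, j = np.unravel_index(int(np.argmax(env)), env.shape)
    if i in (0, env.shape[0] - 1) or j in (0, env.shape[1] - 1):
        raise BorderPeakError(f"peak at index ({i}, {j}) lies on the image border")

    da, va = _parabolic_offset(env[i - 1, j], env[i, j], env[i + 1, j])
    dl, vl = _parabolic_offset(env[i, j - 1], env[i, j], env[i, j + 1])
    peak_a = grid.lateral[i] + da * (grid.lateral[i + 1] - grid.lateral[i]
                                     if da >= 0 else grid.lateral[i] - grid.lateral[i - 1])
    peak_l = grid.depth[j] + dl * (grid.depth[j + 1] - grid.depth[j]
                                   if dl >= 0 else grid.depth[j] - grid.depth[j - 1])
    v_peak = max(va, vl, env[i, j])

    half = v_peak / 2.0
    lat_prof, ax_prof = env[:, j], env[i, :]
    crossings_lat = (
        _half_crossing(lat_prof, grid.lateral, i, half, -1),
        _half_crossing(lat_prof, grid.lateral, i, half, +1),
    )
    crossings_ax = (
        _half_crossing(ax_prof, grid.depth, j, half, -1),
        _half_crossing(ax_prof, grid.depth, j, half, +1),
    )
    if None in crossings_lat or None in crossings_ax:
        raise ValueError("half-maximum level is not reached inside the image")
    fwhm_lat = crossings_lat[1] - crossings_lat[0]
    fwhm_ax = crossings_ax[1] - crossings_ax[0]

    # main-lobe support: rectangle bounded by the first local minima
    i_lo = _first_local_min(lat_prof, i, -1)
    i_hi = _first_local_min(lat_prof, i, +1)
    j_lo = _first_local_min(ax_prof, j, -1)
    j_hi = _first_local_min(ax_prof, j, +1)
    mask = np.ones_like(env, dtype=bool)
    mask[i_lo : i_hi + 1, j_lo : j_hi + 1] = False
    sidelobe = float(env[mask].max()) if mask.any() else 0.0
    pslr = np.inf if sidelobe == 0 else 20.0 * np.log10(v_peak / sidelobe)

    err = float(np.hypot(peak_a - true_position[0], peak_l - true_position[1]))
    return PSFReport(
        peak_lateral=float(peak_a),
        peak_depth=float(peak_l),
        localization_error=err,
        fwhm_lateral=float(fwhm_lat),
        fwhm_axial=float(fwhm_ax),
        pslr_db=float(pslr),
    )


def contrast_ratio(
    env: np.ndarray,
    grid: ImageGrid,
    inside: tuple[float, float, float],
    outside: tuple[float, float, float, float],
) -> float:
    """Contrast of a disk against a surrounding ring, in dB.

    ``inside = (center_a, center_l, radius)``; ``outside = (center_a,
    center_l, inner_radius, outer_radius)``.  Returns
    ``20 log10(mean_inside / mean_outside)``; more negative means a darker
    (e.g. anechoic) disk.
    """
    env = np.asarray(env, dtype=float)
    a, l = grid.mesh()
    ca, cl, r = inside
    m_in = (a - ca) ** 2 + (l - cl) ** 2 <= r**2
    oa, ol, r0, r1 = outside
    d2 = (a - oa) ** 2 + (l - ol) ** 2
    m_out = (d2 >= r0**2) & (d2 <= r1**2) & ~m_in
    if not m_in.any() or not m_out.any():
        raise ValueError("inside/outside regions must both be nonempty")
    mi, mo = env[m_in].mean(), env[m_out].mean()
    if mo <= 0:
        raise ValueError("outside region has zero mean envelope")
    if mi <= 0:
        return -np.inf
    return float(20.0 * np.log10(mi / mo))
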