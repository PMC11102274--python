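"""Self-describing on-disk formats and run configuration.

Channel-data container (normative layout, HDF5)
-----------------------------------------------
* dataset ``/channel_data``: float32, shaped ``[n_angles, n_elements, n_samples]``
* root attributes: ``sampling_rate_hz``, ``sound_speed_m_s``, ``pitch_m``,
  ``n_elements``, ``center_offset_m``, ``t0_s``, ``angles_rad`` (array, one
  entry per panel), ``pulse_center_hz``
* optional dataset ``/scatterers``: float64 ``[n, 3]`` columns
  ``(a_w, l_w, amplitude)`` — the ground truth when the file came from the
  simulator.

Images are exported as 16-bit grayscale TIFF or PNG after log compression,
with a JSON sidecar carrying the grid axes, method, angles and dynamic range
so the pixel values remain interpretable.

The run configuration is a flat key/value YAML document; every key is a
scalar or a short list (see :class:`RunConfig`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from PIL import Image

from .das import BeamformedImage
from .geometry import ImageGrid, LinearArray, Medium
from .metrics import envelope_image, log_compress
from .simulate import ChannelData, Scatterer

__all__ = [
    "FormatError",
    "RunConfig",
    "write_channel_h5",
    "read_channel_h5",
    "export_image",
]


class FormatError(ValueError):
    """A channel-data file violates the documented layout."""


_REQUIRED_ATTRS = (
    "sampling_rate_hz",
    "sound_speed_m_s",
    "pitch_m",
    "n_elements",
    "center_offset_m",
    "t0_s",
    "angles_rad",
    "pulse_center_hz",
)


def write_channel_h5(
    path,
    channels: list[ChannelData],
    scatterers: list[Scatterer] | None = None,
    pulse_center_hz: float = float("nan"),
) -> None:
    """Write one panel per plane-wave angle to the documented HDF5 layout."""
    if not channels:
        raise ValueError("need at least one channel-data panel")
    first = channels[0]
    for ch in channels[1:]:
        if (
            ch.array != first.array
            or ch.medium != first.medium
            or ch.sampling_rate != first.sampling_rate
            or ch.t0 != first.t0
            or ch.n_samples != first.n_samples
        ):
            raise ValueError("all panels must share array, medium, fs, t0 and length")
    data = np.stack([ch.samples for ch in channels]).astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("channel_data", data=data)
        f.attrs["sampling_rate_hz"] = first.sampling_rate
        f.attrs["sound_speed_m_s"] = first.medium.sound_speed
        f.attrs["pitch_m"] = first.array.pitch
        f.attrs["n_elements"] = first.array.n_elements
        f.attrs["center_offset_m"] = first.array.center_offset
        f.attrs["t0_s"] = first.t0
        f.attrs["angles_rad"] = np.array([ch.angle for ch in channels])
        f.attrs["pulse_center_hz"] = pulse_center_hz
        if scatterers is not None:
            f.create_dataset(
                "scatterers",
                data=np.array([[s.a_w, s.l_w, s.amplitude] for s in scatterers],
                              dtype=np.float64).reshape(-1, 3),
            )


def read_channel_h5(path) -> tuple[list[ChannelData], list[Scatterer] | None]:
    """Read a channel-data file back into per-angle panels (stored precision)."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"missing required root attribute {name!r}")
        if "channel_data" not in f:
            raise FormatError("missing dataset 'channel_data'")
        data = np.asarray(f["channel_data"], dtype=float)
        if data.ndim != 3:
            raise FormatError("dataset 'channel_data' must be 3-D [angle, element, sample]")
        angles = np.atleast_1d(np.asarray(f.attrs["angles_rad"], dtype=float))
        if data.shape[0] != angles.size:
            raise FormatError(
                f"angles_rad has {angles.size} entries but channel_data holds "
                f"{data.shape[0]} panels"
            )
        n_el = int(f.attrs["n_elements"])
        if data.shape[1] != n_el:
            raise FormatError(
                f"n_elements={n_el} but channel_data panels have {data.shape[1]} rows"
            )
        array = LinearArray(
            n_elements=n_el,
            pitch=float(f.attrs["pitch_m"]),
            center_offset=float(f.attrs["center_offset_m"]),
        )
        medium = Medium(sound_speed=float(f.attrs["sound_speed_m_s"]))
        channels = [
            ChannelData(
                samples=data[i],
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                t0=float(f.attrs["t0_s"]),
                angle=float(angles[i]),
                array=array,
                medium=medium,
            )
            for i in range(angles.size)
        ]
        scatterers = None
        if "scatterers" in f:
            raw = np.asarray(f["scatterers"], dtype=float).reshape(-1, 3)
            scatterers = [Scatterer(*row) for row in raw]
    return channels, scatterers


def export_image(
    img: BeamformedImage,
    path,
    sidecar_path=None,
    dynamic_range_db: float = 60.0,
) -> None:
    """Export a B-mode rendering (16-bit grayscale TIFF/PNG) plus JSON sidecar.

    The envelope is log-compressed to ``dynamic_range_db`` and mapped
    linearly so the maximum becomes 65535 and the -DR floor becomes 0.  The
    written raster is transposed to (depth, lateral) so depth runs down the
    image, as in a clinical display.
    """
    env = envelope_image(img)
    db = log_compress(env, dynamic_range_db)
    scaled = np.round((db + dynamic_range_db) / dynamic_range_db * 65535.0)
    raster = scaled.astype(np.uint16).T  # rows = depth
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    elif path.suffix.lower() == ".png":
        Image.fromarray(raster).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r} (use .tiff or .png)")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "lateral_m": img.grid.lateral.tolist(),
                "depth_m": img.grid.depth.tolist(),
                "method": img.method,
                "angles_rad": list(img.angles),
                "dynamic_range_db": dynamic_range_db,
                "dtype": "uint16",
                "orientation": "rows=depth, cols=lateral",
            },
            indent=2,
        )
    )


@dataclass
class RunConfig:
    """Flat run configuration for the CLI (all lengths m, frequencies Hz).

    Defaults describe the package's reference desk-scale acquisition: a
    128-element, 0.3 mm pitch array at 5 MHz / 60 % bandwidth, fs = 4 f0,
    1540 m/s medium, three steering angles of -10/0/+10 degrees, and a
    quarter-wavelength image grid around a single point target.
    """

    n_elements: int = 128
    pitch_m: float = 0.3e-3
    center_offset_m: float = 0.0
    sound_speed_m_s: float = 1540.0
    center_frequency_hz: float = 5.0e6
    fractional_bandwidth: float = 0.6
    sampling_rate_hz: float = 20.0e6
    angles_deg: list = field(default_factory=lambda: [-10.0, 0.0, 10.0])
    aperture_half_width_m: float | str = "full"
    apodization: str = "rectangular"
    grid_lateral_min_m: float = -5.0e-3
    grid_lateral_max_m: float = 5.0e-3
    grid_depth_min_m: float = 20.0e-3
    grid_depth_max_m: float = 30.0e-3
    grid_spacing_m: float = 77.0e-6
    phantom: str = "point"  # "point" or "speckle"
    point_lateral_m: float = 0.0
    point_depth_m: float = 25.0e-3
    speckle_density_per_m2: float = 5.0e6
    anechoic_disks: list = field(default_factory=list)  # [a, l, r] triples
    noise_std: float = 0.0
    dynamic_range_db: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pitch_m",
            "sound_speed_m_s",
            "center_frequency_hz",
            "sampling_rate_hz",
            "grid_spacing_m",
            "dynamic_range_db",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not self.angles_deg:
            raise ValueError("angle list must be nonempty")

    # -- construction helpers ------------------------------------------------
    def array(self) -> LinearArray:
        return LinearArray(self.n_elements, self.pitch_m, self.center_offset_m)

    def medium(self) -> Medium:
        return Medium(self.sound_speed_m_s)

    def pulse(self):
        from .geometry import Pulse

        return Pulse(self.center_frequency_hz, self.fractional_bandwidth,
                     self.sampling_rate_hz)

    def grid(self) -> ImageGrid:
        return ImageGrid.regular(
            self.grid_lateral_min_m,
            self.grid_lateral_max_m,
            self.grid_depth_min_m,
            self.grid_depth_max_m,
            self.grid_spacing_m,
        )

    def angles_rad(self) -> list[float]:
        return [float(np.deg2rad(a)) for a in self.angles_deg]

    # -- (de)serialisation ---------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
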