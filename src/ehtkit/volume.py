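"""Multi-channel 3D intensity volumes with physical voxel spacing.

The canonical axis order is ``(channel, z, y, x)``; an optional leading time
axis gives ``(time, channel, z, y, x)``.  Spacing is always expressed in
micrometres per voxel along ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from ehtkit.exceptions import ConfigurationError

__all__ = ["VolumeStack"]


@dataclass
class VolumeStack:
    """A fluorescence volume: ``data[(t,) c, z, y, x]`` with µm spacing.

    Parameters
    ----------
    data
        Non-negative intensity array, ``(c, z, y, x)`` or ``(t, c, z, y, x)``.
    spacing_um
        Physical voxel size ``(z, y, x)`` in micrometres.
    channel_names
        Optional channel labels, e.g. ``("junction", "nucleus")``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ConfigurationError(
                f"expected (c, z, y, x) or (t, c, z, y, x) array, got ndim={self.data.ndim}"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ConfigurationError(f"spacing must be three positive lengths, got {self.spacing_um}")
        if self.channel_names and len(self.channel_names) != self.n_channels:
            raise ConfigurationError("channel_names length does not match channel axis")

    # -- geometry ----------------------------------------------------------

    @property
    def has_time(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_channels(self) -> int:
        return self.data.shape[1] if self.has_time else self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel(self, index: int, time: int | None = None) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        if self.has_time:
            return self.data[0 if time is None else time, index]
        return self.data[index]

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Extent of the volume along (z, y, x), in µm."""
        nz, ny, nx = self.shape_zyx
        sz, sy, sx = self.spacing_um
        return (nz * sz, ny * sy, nx * sx)

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with voxel-size metadata."""
        sz, sy, sx = self.spacing_um
        axes = "TCZYX" if self.has_time else "CZYX"
        tifffile.imwrite(
            path,
            np.asarray(self.data, dtype=np.float32),
            ome=True,
            metadata={
                "axes": axes,
                "PhysicalSizeX": sx,
                "PhysicalSizeY": sy,
                "PhysicalSizeZ": sz,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZUnit": "µm",
            },
        )

    @classmethod
    def from_tiff(cls, path, spacing_um: tuple[float, float, float] | None = None) -> "VolumeStack":
        """Read an OME-TIFF written by :meth:`to_tiff` (or compatible)."""
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            if spacing_um is None:
                try:
                    import xml.etree.ElementTree as ET

                    root = ET.fromstring(tif.ome_metadata)
                    ns = {"ome": root.tag.split("}")[0].strip("{")}
                    px = root.find(".//ome:Pixels", ns)
                    spacing_um = (
                        float(px.get("PhysicalSizeZ")),
                        float(px.get("PhysicalSizeY")),
                        float(px.get("PhysicalSizeX")),
                    )
                except Exception as exc:  # pragma: no cover - metadata variants
                    raise ConfigurationError(
                        "could not recover voxel spacing from metadata; pass spacing_um"
                    ) from exc
        if data.ndim == 3:
            data = data[np.newaxis]
        return cls(data=data, spacing_um=spacing_um)
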