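"""Volumetric image containers for serial block-face EM stacks.

A stack is stored section-major, ``(z, y, x)``: axis 0 walks through the
block in cutting order, so each 2D slice is one block-face image.  In the
retinal volumes this package targets, low z is the ganglion cell layer
(GCL), the middle is the inner plexiform layer (IPL) and high z reaches
the inner nuclear layer (INL).  Physical scale is carried as nanometres
per voxel along each axis; every derived quantity (areas, volumes, Sholl
radii) is reported in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

GCL = "GCL"
IPL = "IPL"
INL = "INL"


@dataclass(frozen=True)
class LayerAnnotation:
    """Retinal layer boundaries along the sectioning (z) axis.

    Parameters
    ----------
    gcl_ipl : int
        Index of the first section belonging to the IPL.
    ipl_inl : int
        Index of the first section belonging to the INL.
    n_sections : int
        Total number of sections in the stack.

    The three layers partition ``[0, n_sections)``:
    ``[0, gcl_ipl)`` is GCL, ``[gcl_ipl, ipl_inl)`` is IPL and
    ``[ipl_inl, n_sections)`` is INL.
    """

    gcl_ipl: int
    ipl_inl: int
    n_sections: int

    def __post_init__(self) -> None:
        if not (0 < self.gcl_ipl < self.ipl_inl < self.n_sections):
            raise ValueError(
                "layer boundaries must satisfy 0 < gcl_ipl < ipl_inl < n_sections, "
                f"got {self.gcl_ipl}, {self.ipl_inl}, {self.n_sections}"
            )

    def layer_of(self, z: int) -> str:
        """Return the layer name containing section ``z``."""
        if not 0 <= z < self.n_sections:
            raise ValueError(f"section {z} outside stack of {self.n_sections}")
        if z < self.gcl_ipl:
            return GCL
        if z < self.ipl_inl:
            return IPL
        return INL

    def ipl_depth(self, z) -> np.ndarray:
        """Normalized IPL depth of section(s) ``z``.

        Depth runs from 0 at the IPL/INL border to 1 at the GCL/IPL
        border, the convention under which the OFF sublamina occupies
        low depths (near the INL) and the ON sublamina high depths
        (near the GCL).  Values are clipped to [0, 1] so sections just
        outside the IPL map onto the nearest border.
        """
        z = np.asarray(z, dtype=float)
        depth = (self.ipl_inl - z) / (self.ipl_inl - self.gcl_ipl)
        return np.clip(depth, 0.0, 1.0)

    def z_range(self, layer: str) -> tuple[int, int]:
        """Half-open section range ``[start, stop)`` of a layer."""
        ranges = {
            GCL: (0, self.gcl_ipl),
            IPL: (self.gcl_ipl, self.ipl_inl),
            INL: (self.ipl_inl, self.n_sections),
        }
        if layer not in ranges:
            raise ValueError(f"unknown layer {layer!r}")
        return ranges[layer]

    def to_dict(self) -> dict:
        return {
            "gcl_ipl": self.gcl_ipl,
            "ipl_inl": self.ipl_inl,
            "n_sections": self.n_sections,
        }


@dataclass
class VoxelVolume:
    """An 8-bit EM stack with physical voxel size and layer annotation.

    Attributes
    ----------
    data : ndarray, shape (z, y, x), dtype uint8
        Grayscale intensities; dark (low) values mark electron-dense
        label deposit.
    voxel_size_nm : (float, float, float)
        ``(dx, dy, dz)`` — in-plane pixel pitch and section thickness,
        in nanometres.
    layers : LayerAnnotation
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    layers: LayerAnnotation = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")
        dx, dy, dz = self.voxel_size_nm
        if dx <= 0 or dy <= 0 or dz <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.layers is not None and self.layers.n_sections != self.data.shape[0]:
            raise ValueError("layer annotation does not match section count")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def pixel_area_um2(self) -> float:
        dx, dy, _ = self.voxel_size_nm
        return (dx / 1000.0) * (dy / 1000.0)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_nm
        return (dx / 1000.0) * (dy / 1000.0) * (dz / 1000.0)

    @property
    def z_depth_um(self) -> float:
        """Physical extent along the sectioning axis."""
        return self.n_sections * self.voxel_size_nm[2] / 1000.0

    @property
    def physical_volume_um3(self) -> float:
        return self.data.size * self.voxel_volume_um3

    def save(self, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the stack as a multi-page TIFF plus a JSON sidecar."""
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.data)
        sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
        meta = {"voxel_size_nm": list(self.voxel_size_nm)}
        if self.layers is not None:
            meta["layers"] = self.layers.to_dict()
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> "VoxelVolume":
        tiff_path = Path(tiff_path)
        data = tifffile.imread(tiff_path)
        sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        layers = None
        if "layers" in meta:
            layers = LayerAnnotation(**meta["layers"])
        return cls(data=data, voxel_size_nm=tuple(meta["voxel_size_nm"]), layers=layers)


def stack_physical_volume_um3(
    n_sections: int,
    section_thickness_nm: float,
    field_width_um: float,
    field_height_um: float,
) -> float:
    """Physical volume of a serial stack from its acquisition geometry.

    ``n_sections`` block faces of ``field_width_um x field_height_um``
    cut at ``section_thickness_nm`` give a slab of depth
    ``n_sections * thickness``; e.g. 948 sections at 50 nm spanning a
    113.2 x 113.9 um field make a volume of ~6e5 um^3.
    """
    if n_sections <= 0 or section_thickness_nm <= 0:
        raise ValueError("section count and thickness must be positive")
    depth_um = n_sections * section_thickness_nm / 1000.0
    return depth_um * field_width_um * field_height_um
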