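"""Voxel volumes with physical voxel size, and TIFF stack I/O.

Volumes are stored Z-first (``grid[z, y, x]``), matching the slice order of
a reconstructed tomography stack.  On disk a volume is a multi-page TIFF
(one page per Z slice) plus a JSON sidecar carrying ``voxel_size_um`` and
the origin offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "write_volume", "read_volume"]


@dataclass
class VoxelVolume:
    """A 3D scalar lattice with cubic voxels of known physical size.

    ``grid`` is uint8: grayscale 0-255, binary {0, 1}, or labels
    {0 void, 1 foam, 2 cell}.  ``voxel_size`` is the edge length in um.
    """

    grid: np.ndarray
    voxel_size: float  # um per edge
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3D with all dimensions >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.grid, (0, 1)).all())

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3

    @property
    def total_volume_mm3(self) -> float:
        """TV: physical volume of the full reconstructed grid in mm^3."""
        return float(self.grid.size) * self.voxel_volume_mm3


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write as a multi-page TIFF plus a ``<stem>.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.grid.astype(np.uint8), photometric="minisblack")
    sidecar = {
        "voxel_size_um": volume.voxel_size,
        "origin_um": list(volume.origin),
        "shape_zyx": list(volume.grid.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a TIFF stack; voxel size from the sidecar unless given."""
    path = Path(path)
    grid = tifffile.imread(path)
    if grid.ndim == 2:
        grid = grid[None, ...]
    if voxel_size is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"no voxel size given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        voxel_size = float(meta["voxel_size_um"])
        origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    else:
        origin = (0.0, 0.0, 0.0)
    return VoxelVolume(grid, voxel_size, origin)  # type: ignore[arg-type]
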