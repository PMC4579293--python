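"""Binary region-of-interest masks with dissection roles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = ("seed", "waypoint", "termination", "exclusion")


@dataclass
class ROIMask:
    """Binary 3D volume tagged with its role in the dissection protocol.

    Roles follow the virtual-dissection vocabulary: streamlines are launched
    from *seed* voxels, must pass through every *waypoint*, stop (and are
    kept) on entering a *termination* region, and are discarded outright on
    entering an *exclusion* region.
    """

    grid: np.ndarray
    role: str = "waypoint"
    name: str = ""

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("ROI mask must be a 3D volume")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        self.grid = g.astype(bool)

    def with_role(self, role: str) -> "ROIMask":
        return ROIMask(self.grid, role=role, name=self.name)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def region_mask(shape, voxel_size, kind: str, center_mm, size_mm) -> np.ndarray:
    """Rasterise a sphere / box / ellipsoid given in world mm onto the grid.

    Voxel centers sit at ``index * voxel_size``; a voxel belongs to the region
    if its center does.  ``size_mm`` is a radius (sphere), half-extents (box)
    or semi-axes (ellipsoid).
    """
    shape = tuple(int(s) for s in shape)
    vs = np.asarray(voxel_size, dtype=float)
    c = np.asarray(center_mm, dtype=float)
    idx = np.indices(shape, dtype=float)
    world = np.stack([idx[k] * vs[k] for k in range(3)], axis=-1)
    rel = world - c
    if kind == "sphere":
        return np.sum(rel**2, axis=-1) <= float(size_mm) ** 2
    if kind == "box":
        half = np.broadcast_to(np.asarray(size_mm, dtype=float), (3,))
        return np.all(np.abs(rel) <= half, axis=-1)
    if kind == "ellipsoid":
        semi = np.broadcast_to(np.asarray(size_mm, dtype=float), (3,))
        return np.sum((rel / semi) ** 2, axis=-1) <= 1.0
    raise ValueError(f"unknown region kind {kind!r}")
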