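"""Synthetic diffusion-weighted phantoms with known fiber geometry.

The phantom emulates what the downstream dissection analysis assumes about
real data: tubular white-matter bundles with an oriented ("stick")
compartment embedded in an isotropic background, signal-void cavities (the
temporal horn of the lateral ventricle), named ROI placements with dissection
roles, focal lesion cavities, and Rician magnitude noise at a controllable
b=0 SNR.

Forward model per voxel (single shell or multi shell):

    S(g, b) = S0 * [ (1 - f) * exp(-b d)  +  sum_j (f / m) * exp(-b d (g.v_j)^2) ]

where the voxel contains m sticks with unit orientations v_j (m = 1 inside a
single bundle, m = 2 where two bundles cross, sharing the anisotropic
fraction equally), f is the total anisotropic volume fraction and d the
diffusivity in mm^2/s.  Voxels inside a void have S = 0.  Rician noise is
the magnitude of (S + e1, e2) with e ~ N(0, S0/snr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Centerline
from .masks import ROIMask, region_mask, ROLES
from .scheme import AcquisitionScheme


@dataclass(frozen=True)
class BundleSpec:
    """A tubular bundle: smooth centerline (world mm), radius, stick fraction f,
    diffusivity d (mm^2/s)."""

    centerline: np.ndarray
    radius: float
    stick_fraction: float = 0.7
    diffusivity: float = 1.7e-3

    def __post_init__(self):
        cp = np.asarray(self.centerline, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
            raise ValueError("bundle centerline needs >= 2 control points")
        if self.radius <= 0:
            raise ValueError("bundle radius must be positive")
        if not 0.0 <= self.stick_fraction <= 1.0:
            raise ValueError("stick fraction must lie in [0, 1]")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        object.__setattr__(self, "centerline", cp)


@dataclass(frozen=True)
class RegionSpec:
    """A named sphere/box/ellipsoid placement in world mm."""

    name: str
    kind: str
    center: tuple
    size: object
    role: str = "waypoint"


@dataclass
class PhantomSpec:
    """Complete description of a synthetic acquisition.

    ``snr`` is the b=0 signal-to-noise ratio (``math.inf`` for noiseless);
    ``background_diffusivity`` sets the isotropic signal decay outside all
    bundles.  All coordinates are RAS world millimetres; voxel centers sit at
    ``index * voxel_size``; a coronal slice is a fixed second-axis index.
    """

    grid_shape: tuple
    voxel_size: tuple = (1.0, 1.0, 1.0)
    bundles: dict = field(default_factory=dict)
    void_regions: list = field(default_factory=list)
    roi_specs: list = field(default_factory=list)
    lesion_specs: list = field(default_factory=list)
    snr: float = math.inf
    rng_seed: int = 0
    s0: float = 100.0
    background_diffusivity: float = 0.9e-3

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not (self.snr > 0):
            raise ValueError("snr must be positive (or infinite)")
        for r in self.roi_specs:
            if r.role not in ROLES:
                raise ValueError(f"ROI {r.name!r} has invalid role {r.role!r}")
        self._check_placements()

    def _extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_size)

    def _check_placements(self):
        hi = self._extent_mm()
        for r in list(self.roi_specs) + list(self.void_regions) + list(self.lesion_specs):
            c = np.asarray(r.center, dtype=float)
            if np.any(c < 0) or np.any(c > hi):
                raise ValueError(f"placement {r.name!r} center outside grid")


@dataclass
class DWVolume:
    """4D diffusion signal plus its acquisition scheme and voxel geometry."""

    data: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError("data must be (X, Y, Z, n_volumes)")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass
class GroundTruth:
    """Known phantom geometry for validating the pipeline."""

    occupancy: dict                 # bundle name -> bool volume
    centerlines: dict               # bundle name -> Centerline
    slice_profiles: dict            # bundle name -> DataFrame(slice_y, x_mm, z_mm)
    rois: dict                      # roi name -> ROIMask
    lesions: dict                   # lesion name -> ROIMask
    void: np.ndarray                # bool volume
    tangent_info: dict              # bundle name -> (dist volume, tangent volume)


def _voxel_centers(shape, voxel_size) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    return np.stack([idx[k] * vs[k] for k in range(3)], axis=-1).reshape(-1, 3)


def _bundle_fields(spec: PhantomSpec):
    """Occupancy, distance and tangent volumes for every bundle."""
    shape = spec.grid_shape
    centers = _voxel_centers(shape, spec.voxel_size)
    hi = spec._extent_mm()
    lo = np.zeros(3)
    out = {}
    for name, b in spec.bundles.items():
        cl = Centerline(b.centerline)
        if np.any(cl.points - b.radius < lo - 0.5 * np.asarray(spec.voxel_size)) or np.any(
            cl.points + b.radius > hi + 0.5 * np.asarray(spec.voxel_size)
        ):
            raise ValueError(f"bundle {name!r} leaves the grid")
        dist, tang = cl.distance_and_tangent(centers)
        occ = (dist <= b.radius).reshape(shape)
        out[name] = (cl, occ, dist.reshape(shape), tang.reshape(shape + (3,)))
    return out


def _void_mask(spec: PhantomSpec) -> np.ndarray:
    void = np.zeros(spec.grid_shape, dtype=bool)
    for r in spec.void_regions:
        void |= region_mask(spec.grid_shape, spec.voxel_size, r.kind, r.center, r.size)
    return void


def build_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Geometry-only evaluation of a spec (no signal simulation)."""
    fields = _bundle_fields(spec)
    void = _void_mask(spec)
    vs = np.asarray(spec.voxel_size)
    occupancy, centerlines, profiles, tangent_info = {}, {}, {}, {}
    for name, (cl, occ, dist, tang) in fields.items():
        occupancy[name] = occ
        centerlines[name] = cl
        tangent_info[name] = (dist, tang)
        rows = []
        ys = np.unique(np.nonzero(occ)[1])
        for y in ys:
            pt = cl.point_at_plane(axis=1, coord=y * vs[1])
            if pt is not None:
                rows.append({"slice_y": int(y), "x_mm": pt[0], "z_mm": pt[2]})
        profiles[name] = pd.DataFrame(rows)
    rois = {}
    for r in spec.roi_specs:
        grid = region_mask(spec.grid_shape, spec.voxel_size, r.kind, r.center, r.size)
        if np.any(grid & void):
            raise ValueError(f"ROI {r.name!r} overlaps a void region")
        rois[r.name] = ROIMask(grid, role=r.role, name=r.name)
    lesions = {
        r.name: ROIMask(
            region_mask(spec.grid_shape, spec.voxel_size, r.kind, r.center, r.size),
            role="exclusion",
            name=r.name,
        )
        for r in spec.lesion_specs
    }
    return GroundTruth(occupancy, centerlines, profiles, rois, lesions, void, tangent_info)


def simulate_phantom(spec: PhantomSpec, scheme: AcquisitionScheme):
    """Simulate the 4D signal for a spec under a scheme.

    Returns ``(DWVolume, GroundTruth)``.  Deterministic for a given
    ``spec.rng_seed``; noiseless voxels outside all bundles are isotropic.
    """
    gt = build_ground_truth(spec)
    shape = spec.grid_shape
    nvox = int(np.prod(shape))
    bvals = np.asarray(scheme.bvalues)
    bvecs = np.asarray(scheme.bvectors)
    nvol = scheme.n_volumes

    f_tot = np.zeros(nvox)
    d_vox = np.full(nvox, spec.background_diffusivity)
    members = []  # (flat indices, tangents) per bundle
    count = np.zeros(nvox, dtype=int)
    f_sum = np.zeros(nvox)
    d_sum = np.zeros(nvox)
    for name, b in spec.bundles.items():
        occ = gt.occupancy[name].reshape(-1)
        tang = gt.tangent_info[name][1].reshape(-1, 3)
        idx = np.nonzero(occ)[0]
        members.append((idx, tang[idx], b))
        count[idx] += 1
        f_sum[idx] += b.stick_fraction
        d_sum[idx] += b.diffusivity
    inb = count > 0
    f_tot[inb] = f_sum[inb] / count[inb]
    d_vox[inb] = d_sum[inb] / count[inb]

    # isotropic ball term everywhere
    signal = spec.s0 * (1.0 - f_tot)[:, None] * np.exp(-np.outer(d_vox, bvals))
    # stick terms, split equally between member bundles
    for idx, tang, b in members:
        c = tang @ bvecs.T  # (n_in_bundle, nvol)
        stick = np.exp(-d_vox[idx, None] * bvals[None, :] * c**2)
        signal[idx] += spec.s0 * (f_tot[idx] / count[idx])[:, None] * stick

    signal = signal.reshape(shape + (nvol,))
    signal[gt.void] = 0.0

    if math.isfinite(spec.snr):
        rng = np.random.default_rng(spec.rng_seed)
        sigma = spec.s0 / spec.snr
        e1 = rng.normal(0.0, sigma, size=signal.shape)
        e2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)

    return DWVolume(signal, scheme, spec.voxel_size), gt


def brain_mask(spec: PhantomSpec, gt: GroundTruth | None = None) -> ROIMask:
    """Everything on the grid except signal voids."""
    gt = gt or build_ground_truth(spec)
    return ROIMask(~gt.void, role="waypoint", name="brain")


def make_lesion(spec: PhantomSpec, target_bundle: str, on_path: bool) -> ROIMask:
    """Place a focal cavity that either transects the bundle or misses it.

    On-path: a box that fully covers the bundle's occupancy in at least one
    coronal slice (the slice at the middle of the bundle's y-extent).
    Off-path: a sphere placed by a deterministic scan at the first grid
    position disjoint from the bundle.
    """
    if target_bundle not in spec.bundles:
        raise ValueError(f"no bundle named {target_bundle!r} in spec")
    gt = build_ground_truth(spec)
    occ = gt.occupancy[target_bundle]
    vs = np.asarray(spec.voxel_size)
    shape = spec.grid_shape
    if on_path:
        ys = np.unique(np.nonzero(occ)[1])
        if ys.size == 0:
            raise ValueError("bundle has no occupancy on the grid")
        y_star = int(ys[len(ys) // 2])
        ii, kk = np.nonzero(occ[:, y_star, :])
        grid = np.zeros(shape, dtype=bool)
        i0, i1 = max(ii.min() - 1, 0), min(ii.max() + 2, shape[0])
        k0, k1 = max(kk.min() - 1, 0), min(kk.max() + 2, shape[2])
        y0, y1 = max(y_star - 1, 0), min(y_star + 2, shape[1])
        grid[i0:i1, y0:y1, k0:k1] = True
        return ROIMask(grid, role="exclusion", name=f"lesion_on_{target_bundle}")
    radius = 3.0 * float(vs.min())
    step = max(int(round(radius / vs.min())), 1)
    for i in range(step, shape[0] - step, step):
        for j in range(step, shape[1] - step, step):
            for k in range(step, shape[2] - step, step):
                grid = region_mask(shape, vs, "sphere", np.array([i, j, k]) * vs, radius)
                if grid.any() and not np.any(grid & occ):
                    return ROIMask(grid, role="exclusion", name=f"lesion_off_{target_bundle}")
    raise ValueError("no off-path lesion placement fits the grid")


def ground_truth_field(spec: PhantomSpec, K: int = 1, gt: GroundTruth | None = None):
    """Build an idealised orientation field directly from the geometry.

    Inside a bundle every sample is the local centerline tangent (samples
    cycle through member bundles in crossing voxels); outside, orientations
    are irrelevant placeholders with f = 0.  Used as an oracle field for
    tracker tests, bypassing the model fit.
    """
    from .modelfit import OrientationField  # local import to avoid a cycle
    from . import rng as crng

    gt = gt or build_ground_truth(spec)
    shape = spec.grid_shape
    nvox = int(np.prod(shape))
    vecs = np.zeros((nvox, K, 3), dtype=np.float32)
    fs = np.zeros((nvox, K), dtype=np.float32)
    # deterministic pseudo-random placeholders for background orientations
    key = crng.hash_key(20240521, np.arange(nvox, dtype=np.uint64))
    bg = crng.normals(key, 0, 3 * K).reshape(nvox, K, 3)
    bg /= np.linalg.norm(bg, axis=-1, keepdims=True) + 1e-12
    vecs[:] = bg.astype(np.float32)

    n_bundles = max(len(spec.bundles), 1)
    tang_stack = np.zeros((nvox, n_bundles, 3))
    f_stack = np.zeros((nvox, n_bundles))
    slot = np.zeros(nvox, dtype=int)
    for name, b in spec.bundles.items():
        occ = gt.occupancy[name].reshape(-1)
        tang = gt.tangent_info[name][1].reshape(-1, 3)
        idx = np.nonzero(occ)[0]
        tang_stack[idx, slot[idx]] = tang[idx]
        f_stack[idx, slot[idx]] = b.stick_fraction
        slot[idx] += 1
    inb = np.nonzero(slot > 0)[0]
    for k in range(K):
        pick = k % slot[inb]  # crossing voxels: samples cycle through members
        vecs[inb, k] = tang_stack[inb, pick].astype(np.float32)
        fs[inb, k] = f_stack[inb, pick].astype(np.float32)
    mask = ~gt.void
    s0 = np.full(shape, spec.s0)
    d = np.full(shape, spec.background_diffusivity)
    return OrientationField(
        orientations=vecs.reshape(shape + (K, 3)),
        fractions=fs.reshape(shape + (K,)),
        s0=s0,
        d=d,
        brain_mask=mask,
        K=K,
        voxel_size=spec.voxel_size,
    )
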