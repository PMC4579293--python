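"""Diffusion acquisition schemes (b-values and gradient directions).

A scheme is the per-volume diffusion weighting of a 4D acquisition: ``n_b0``
unweighted volumes followed by diffusion-weighted volumes whose unit gradient
directions are spread quasi-uniformly over the hemisphere by electrostatic
repulsion (antipodally symmetric Coulomb energy), the standard construction
when a vendor direction table is not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    b=0 volumes carry a zero direction vector.  Invariants are enforced at
    construction: matching lengths, unit vectors on weighted volumes, and at
    least one b=0 volume.
    """

    bvalues: np.ndarray
    bvectors: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvalues, dtype=float)
        bvecs = np.asarray(self.bvectors, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3 or len(bvals) != len(bvecs):
            raise ValueError("bvalues and bvectors must align as (N,), (N, 3)")
        if not np.any(bvals == 0):
            raise ValueError("scheme needs at least one b=0 volume")
        norms = np.linalg.norm(bvecs[bvals > 0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions of weighted volumes must be unit vectors")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "bvectors", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0


def _repulsion(points: np.ndarray, n_iter: int = 300, step: float = 5e-3) -> np.ndarray:
    """Relax unit vectors under antipodal Coulomb repulsion (fixed iterations)."""
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]          # v_i - v_j
        dsum = p[:, None, :] + p[None, :, :]          # v_i + v_j (antipode term)
        d2 = np.sum(diff * diff, axis=-1) + np.eye(len(p))
        s2 = np.sum(dsum * dsum, axis=-1) + 1e-12
        force = np.sum(diff / d2[..., None] ** 2, axis=1) + np.sum(dsum / s2[..., None] ** 2, axis=1)
        # project onto tangent plane and take a small normalized step
        force -= p * np.sum(force * p, axis=1, keepdims=True)
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        p = p + step * force / norm
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_scheme(n_directions: int, bvalue: float, n_b0: int, rng_seed: int) -> AcquisitionScheme:
    """Build a scheme of ``n_b0`` b=0 volumes plus ``n_directions`` weighted ones.

    Directions start from a seeded random configuration and are relaxed by
    electrostatic repulsion treating v and -v as identical; deterministic for
    a given seed.
    """
    if n_directions < 6:
        raise ValueError("insufficient directions for orientation fitting")
    if bvalue <= 0:
        raise ValueError("bvalue must be positive")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    rng = np.random.default_rng(rng_seed)
    init = rng.standard_normal((n_directions, 3))
    dirs = _repulsion(init)
    # canonical hemisphere: flip so z >= 0 (ties broken on y then x)
    flip = (dirs[:, 2] < 0) | ((dirs[:, 2] == 0) & (dirs[:, 1] < 0))
    dirs[flip] *= -1.0
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(bvals, bvecs)


def min_pairwise_angle_deg(bvecs: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) between directions, mod sign."""
    v = np.asarray(bvecs, dtype=float)
    v = v[np.linalg.norm(v, axis=1) > 0]
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    c = np.abs(v @ v.T)
    np.fill_diagonal(c, 0.0)
    return float(np.degrees(np.arccos(np.clip(c.max(initial=0.0), -1, 1)))) if len(v) > 1 else 90.0


def save_fsl(scheme: AcquisitionScheme, bvals_path, bvecs_path) -> None:
    """Write FSL-dialect text files: bvals one row; bvecs three rows (x, y, z)."""
    np.savetxt(bvals_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvectors.T, fmt="%.8f")


def load_fsl(bvals_path, bvecs_path) -> AcquisitionScheme:
    """Read an FSL bvals/bvecs pair."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is row-per-axis
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs)
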