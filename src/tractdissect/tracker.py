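"""Probabilistic streamline propagation and visitation-count accumulation.

Streamlines are launched from the center of every seed voxel (a fixed number
of samples per voxel), propagated in both directions from the initial point,
and concatenated.  At each step one orientation sample is drawn from the
current voxel's posterior (nearest-voxel lookup), sign-aligned with the
previous direction, and followed for one step; propagation stops when the
cosine between successive directions falls below the curvature threshold,
when the streamline leaves the brain mask or grid, on entering a
termination-role mask (the streamline is kept), or at the step cap.
A streamline is discarded if it ever enters an exclusion mask and retained
only if it visits every waypoint mask; each retained streamline increments
each visited voxel's count at most once.

Per-streamline randomness is a counter-based stream keyed on
``(rng_seed, seed-voxel flat index, sample index)`` — reproducible and
independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import rng as crng
from .masks import ROIMask
from .modelfit import OrientationField


@dataclass
class TrackerConfig:
    """Propagation settings.

    ``curvature_threshold`` is the minimum cosine between successive step
    directions (0.2 by default, the standard probabilistic-tractography
    setting); ``step_size`` defaults to half the smallest voxel dimension.
    """

    curvature_threshold: float = 0.2
    samples_per_seed_voxel: int = 5000
    step_size: float | None = None
    max_steps: int = 2000
    rng_seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature threshold must lie in [-1, 1]")
        if self.samples_per_seed_voxel < 1:
            raise ValueError("need at least one sample per seed voxel")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step size must be positive")

    def resolved_step(self, voxel_size) -> float:
        return self.step_size if self.step_size is not None else 0.5 * float(min(voxel_size))

    def snapshot(self) -> dict:
        return {
            "curvature_threshold": self.curvature_threshold,
            "samples_per_seed_voxel": self.samples_per_seed_voxel,
            "step_size": self.step_size,
            "max_steps": self.max_steps,
            "rng_seed": self.rng_seed,
        }


@dataclass
class VisitationMap:
    """Per-voxel count of retained streamlines plus bookkeeping."""

    counts: np.ndarray
    n_seed_samples: int
    n_retained: int
    config: dict = dc_field(default_factory=dict)
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.counts.max(initial=0) > self.n_retained:
            raise ValueError("voxel count exceeds number of retained streamlines")

    @property
    def grid_shape(self) -> tuple:
        return self.counts.shape

    def binarized(self) -> np.ndarray:
        return self.counts > 0


def _stream_counter(side: int, step: int, max_steps: int) -> np.uint64:
    # counter 0 is the initial draw; sides get disjoint step ranges
    return np.uint64(1 + side * (max_steps + 2) + step)


def propagate_one(field: OrientationField, start, config: TrackerConfig, rng_state) -> tuple:
    """Propagate a single streamline in one direction from ``start`` (world mm).

    ``rng_state`` is either a uint64 stream key or a tuple of integers from
    which one is derived.  Returns ``(polyline, reason)`` where reason is one
    of ``"exited" | "curvature" | "terminated" | "max_steps"``.
    """
    key = rng_state if np.isscalar(rng_state) else crng.hash_key(*rng_state)
    vs = np.asarray(field.voxel_size)
    shape = np.asarray(field.grid_shape)
    step = config.resolved_step(field.voxel_size)
    pos = np.asarray(start, dtype=float)
    idx = np.round(pos / vs).astype(int)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("start point outside field grid")
    vecs = field.orientations.reshape(-1, field.K, 3)
    nvox_shape = tuple(field.grid_shape)
    pts = [pos.copy()]
    prev = None
    for t in range(config.max_steps):
        idx = np.round(pos / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return np.array(pts), "exited"
        flat = int(np.ravel_multi_index(tuple(idx), nvox_shape))
        if not field.brain_mask.reshape(-1)[flat]:
            return np.array(pts), "exited"
        k = int(crng.randint(np.uint64(key), _stream_counter(0, t, config.max_steps) if prev is not None else np.uint64(0), field.K))
        v = vecs[flat, k].astype(float)
        nv = np.linalg.norm(v)
        if nv == 0:
            return np.array(pts), "exited"
        v = v / nv
        if prev is not None:
            if float(prev @ v) < 0:
                v = -v
            if float(prev @ v) < config.curvature_threshold:
                return np.array(pts), "curvature"
        pos = pos + step * v
        prev = v
        pts.append(pos.copy())
    return np.array(pts), "max_steps"


def _as_grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, ROIMask) else np.asarray(mask, bool)


def track(field: OrientationField, seed: ROIMask, waypoints=(), termination: ROIMask | None = None,
          exclusions=(), config: TrackerConfig | None = None) -> VisitationMap:
    """Run the full seeded ensemble and accumulate the visitation map."""
    config = config or TrackerConfig()
    shape = field.grid_shape
    for m in [seed, *waypoints, *([termination] if termination is not None else []), *exclusions]:
        if _as_grid(m).shape != shape:
            raise ValueError("all masks must share the field grid")
    seed_grid = _as_grid(seed)
    if not seed_grid.any():
        raise ValueError("empty seed mask")
    nvox = int(np.prod(shape))
    excl_flat = np.zeros(nvox, dtype=bool)
    for m in exclusions:
        excl_flat |= _as_grid(m).reshape(-1)
    wp_flat = np.zeros(nvox, dtype=np.int64)
    for j, m in enumerate(waypoints):
        g = _as_grid(m).reshape(-1)
        if np.any(g & excl_flat):
            raise ValueError("contradictory mask roles: waypoint overlaps exclusion")
        wp_flat |= g.astype(np.int64) << j
    full_bits = (1 << len(waypoints)) - 1
    term_flat = _as_grid(termination).reshape(-1) if termination is not None else np.zeros(nvox, dtype=bool)
    brain_flat = field.brain_mask.reshape(-1)

    vs = np.asarray(field.voxel_size)
    step = config.resolved_step(field.voxel_size)
    K = field.K
    vecs_flat = field.orientations.reshape(-1, 3)  # (nvox*K, 3)

    seed_flat = np.nonzero(seed_grid.reshape(-1))[0]
    n_per = config.samples_per_seed_voxel
    n_streams = seed_flat.size * n_per
    stream_voxel = np.repeat(seed_flat, n_per)
    sample_idx = np.tile(np.arange(n_per), seed_flat.size)
    keys = crng.hash_key(int(config.rng_seed), stream_voxel.astype(np.uint64), sample_idx.astype(np.uint64))

    ijk0 = np.column_stack(np.unravel_index(stream_voxel, shape)).astype(float)
    pos0 = ijk0 * vs

    excluded = excl_flat[stream_voxel].copy()
    bits = wp_flat[stream_voxel].copy()
    visits = [np.column_stack([np.arange(n_streams), stream_voxel])]

    k0 = crng.randint(keys, np.uint64(0), K)
    v0 = vecs_flat[stream_voxel * K + k0].astype(np.float64)
    v0_norm = np.linalg.norm(v0, axis=1)
    launchable = (v0_norm > 0) & brain_flat[stream_voxel] & ~term_flat[stream_voxel] & ~excluded
    v0 = np.where(v0_norm[:, None] > 0, v0 / np.maximum(v0_norm, 1e-30)[:, None], v0)

    shape_arr = np.asarray(shape)
    for side, sign in ((0, 1.0), (1, -1.0)):
        ids = np.nonzero(launchable)[0]
        if ids.size == 0:
            continue
        prev = sign * v0[ids]
        pos = pos0[ids] + step * prev
        for t in range(config.max_steps):
            if ids.size == 0:
                break
            idx = np.round(pos / vs).astype(np.int64)
            inside = np.all((idx >= 0) & (idx < shape_arr), axis=1)
            ids, pos, prev, idx = ids[inside], pos[inside], prev[inside], idx[inside]
            if ids.size == 0:
                break
            flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
            ok = brain_flat[flat]
            ids, pos, prev, flat = ids[ok], pos[ok], prev[ok], flat[ok]
            if ids.size == 0:
                break
            hit_excl = excl_flat[flat]
            if hit_excl.any():
                excluded[ids[hit_excl]] = True
                keep = ~hit_excl
                ids, pos, prev, flat = ids[keep], pos[keep], prev[keep], flat[keep]
                if ids.size == 0:
                    break
            visits.append(np.column_stack([ids, flat]))
            np.bitwise_or.at(bits, ids, wp_flat[flat])
            hit_term = term_flat[flat]
            if hit_term.any():
                keep = ~hit_term
                ids, pos, prev, flat = ids[keep], pos[keep], prev[keep], flat[keep]
                if ids.size == 0:
                    break
            k = crng.randint(keys[ids], _stream_counter(side, t, config.max_steps), K)
            v = vecs_flat[flat * K + k].astype(np.float64)
            nv = np.linalg.norm(v, axis=1)
            alive = nv > 0
            ids, pos, prev, v, nv = ids[alive], pos[alive], prev[alive], v[alive], nv[alive]
            if ids.size == 0:
                break
            v /= nv[:, None]
            dot = np.sum(prev * v, axis=1)
            v = np.where(dot[:, None] < 0, -v, v)
            dot = np.abs(dot)
            alive = dot >= config.curvature_threshold
            ids, pos, prev, v = ids[alive], pos[alive], prev[alive], v[alive]
            if ids.size == 0:
                break
            pos = pos + step * v
            prev = v

    retained = ~excluded & (bits == full_bits)
    n_retained = int(retained.sum())
    counts = np.zeros(nvox, dtype=np.int32)
    if n_retained and visits:
        pairs = np.concatenate(visits, axis=0)
        keep = retained[pairs[:, 0]]
        pairs = pairs[keep]
        uniq = np.unique(pairs[:, 0].astype(np.int64) * nvox + pairs[:, 1].astype(np.int64))
        np.add.at(counts, (uniq % nvox).astype(np.int64), 1)
    return VisitationMap(counts.reshape(shape), n_streams, n_retained, config.snapshot(), tuple(field.voxel_size))
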