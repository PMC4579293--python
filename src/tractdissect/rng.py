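"""Counter-based random streams for order-independent reproducibility.

Both the voxelwise posterior sampler and the streamline tracker need many
thousands of independent, *named* random streams (one per voxel, one per
seed-voxel/sample pair) whose draws do not depend on the order in which
voxels or streamlines happen to be processed.  A stateless counter-based
construction gives exactly that: every draw is a pure function of
``(stream key, counter)``, so batched and one-at-a-time execution produce
bit-identical results.

The mixer is splitmix64 (Steele, Lea & Flood's finaliser), applied once per
word of key/counter material; output words are mapped to U(0,1) doubles with
53-bit resolution and to normals via Box-Muller.
"""

from __future__ import annotations

import numpy as np

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)


def _mix(x) -> np.ndarray:
    """splitmix64 finaliser; operates elementwise on uint64 (modular, 0-d safe)."""
    z = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = z + _GAMMA
        z = (z ^ (z >> np.uint64(30))) * _M1
        z = (z ^ (z >> np.uint64(27))) * _M2
        return z ^ (z >> np.uint64(31))


def hash_key(*parts) -> np.ndarray:
    """Combine integer parts (scalars or broadcastable uint64 arrays) into a key.

    The combination is sequential absorption: ``h = mix(h ^ part)`` starting
    from a fixed offset, so distinct part tuples give unrelated streams.
    """
    h = np.uint64(0x8C5FB1F8D1985B2D)
    for p in parts:
        arr = np.asarray(p)
        # mask into uint64 without overflow complaints from signed inputs
        part = arr.astype(np.int64, copy=False).view(np.uint64) if arr.dtype.kind in "iu" else np.asarray(p, dtype=np.uint64)
        h = _mix(np.bitwise_xor(h, part))
    return h


def uniforms(key, counter) -> np.ndarray:
    """U(0,1) doubles (53-bit), one per broadcast element of key/counter."""
    h = _mix(np.bitwise_xor(np.asarray(key, dtype=np.uint64), _mix(np.asarray(counter, dtype=np.uint64))))
    return (h >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)


def open_uniforms(key, counter) -> np.ndarray:
    """U(0,1] doubles — safe as Box-Muller log argument."""
    h = _mix(np.bitwise_xor(np.asarray(key, dtype=np.uint64), _mix(np.asarray(counter, dtype=np.uint64))))
    return ((h >> np.uint64(11)).astype(np.float64) + 1.0) * (2.0 ** -53)


def normals(key, counter_base, n: int) -> np.ndarray:
    """n standard normals per key via Box-Muller, counters counter_base+0..n-1.

    Consumes ``2 * ceil(n/2)`` counter slots starting at ``counter_base``.
    Returns shape ``key.shape + (n,)``.
    """
    key = np.asarray(key, dtype=np.uint64)
    m = (n + 1) // 2
    base = np.uint64(counter_base)
    out = np.empty(key.shape + (2 * m,), dtype=np.float64)
    for i in range(m):
        u1 = open_uniforms(key, base + np.uint64(2 * i))
        u2 = uniforms(key, base + np.uint64(2 * i + 1))
        r = np.sqrt(-2.0 * np.log(u1))
        out[..., 2 * i] = r * np.cos(2.0 * np.pi * u2)
        out[..., 2 * i + 1] = r * np.sin(2.0 * np.pi * u2)
    return out[..., :n]


def randint(key, counter, n: int | np.ndarray) -> np.ndarray:
    """Integers in [0, n) per broadcast element (modulo; bias ~n/2^64)."""
    h = _mix(np.bitwise_xor(np.asarray(key, dtype=np.uint64), _mix(np.asarray(counter, dtype=np.uint64))))
    return (h % np.uint64(n)).astype(np.int64) if np.isscalar(n) else (h % np.asarray(n, dtype=np.uint64)).astype(np.int64)
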