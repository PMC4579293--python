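"""The virtual-dissection protocol on visitation maps.

Covers the operations the dissection workflow applies downstream of the
tracker: retaining voxels that carry at least a fraction (default 10%) of
the maximum visitation count; combining opposing seed/termination runs by
binarising, adding and keeping voxels present in both; cross-subject
composites ("present in at least N% of subjects"); and the full pathway
protocol in which the stria terminalis is dissected first and its
unthresholded streamline serves as an exclusion mask for a second
superior-colliculus-to-amygdala dissection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .masks import ROIMask
from .modelfit import OrientationField
from .tracker import TrackerConfig, VisitationMap, track

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StreamlineMask:
    """Binary tract mask with provenance back to its source visitation map(s)."""

    grid: np.ndarray
    provenance: dict = dc_field(default_factory=dict)
    subject: str = ""
    hemisphere: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class DissectionResult:
    """Outcome of the pathway protocol."""

    sc_amygdala: StreamlineMask | None
    stria: StreamlineMask | None
    overlap: StreamlineMask | None
    continuous: bool
    diagnostics: dict = dc_field(default_factory=dict)


def threshold_map(vmap: VisitationMap, fraction: float = 0.10) -> StreamlineMask:
    """Keep voxels whose count is at least ``fraction`` of the maximum count.

    "At least" makes the boundary inclusive: with counts {100, 10, 9} and
    fraction 0.10, the voxel with exactly 10 traces is kept.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    counts = vmap.counts
    max_count = int(counts.max(initial=0))
    if max_count == 0:
        raise ValueError("empty tractogram: visitation map has no nonzero voxel")
    thr = fraction * max_count
    grid = counts >= thr - 1e-9 * max(thr, 1.0)
    return StreamlineMask(grid & (counts > 0), provenance={"threshold_fraction": fraction, "max_count": max_count})


def _continuous(mask: np.ndarray, roi_a: ROIMask, roi_b: ROIMask) -> bool:
    """One 26-connected component touches both endpoint ROIs."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return False
    la = np.unique(labels[roi_a.grid & mask])
    lb = np.unique(labels[roi_b.grid & mask])
    return bool(np.intersect1d(la[la > 0], lb[lb > 0]).size)


def overlap_bidirectional(map_ab: VisitationMap, map_ba: VisitationMap,
                          roi_a: ROIMask, roi_b: ROIMask) -> tuple[StreamlineMask, bool]:
    """Binarise two opposing runs, add, keep voxels present in both (sum = 2).

    ``continuous`` is true iff a single 26-connected component of the overlap
    intersects both endpoint ROIs.
    """
    if map_ab.grid_shape != map_ba.grid_shape:
        raise ValueError("visitation maps are on different grids")
    both = map_ab.binarized() & map_ba.binarized()
    mask = StreamlineMask(both, provenance={"op": "overlap_bidirectional"})
    return mask, _continuous(both, roi_a, roi_b)


def composite(masks, min_fraction: float) -> StreamlineMask:
    """Voxels present in at least ``ceil(min_fraction * n_subjects)`` masks.

    The "at least 8 of the 12 participants" rule is ``min_fraction = 8/12``.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    shape = masks[0].grid.shape
    if any(m.grid.shape != shape for m in masks):
        raise ValueError("composite requires masks on a common grid")
    n = len(masks)
    need = math.ceil(min_fraction * n - 1e-9)
    counts = np.sum([m.grid for m in masks], axis=0)
    return StreamlineMask(counts >= need, provenance={"min_fraction": min_fraction, "n_subjects": n, "need": need})


def dissect_pathway(field: OrientationField, masks: dict, config: TrackerConfig,
                    options: dict | None = None) -> DissectionResult:
    """Run the full pathway protocol.

    ``masks`` must contain ``sc``, ``pulvinar`` and ``amygdala`` ROIMasks;
    the stria-terminalis steps run when ``stria_waypoints`` (list) and
    ``bnst`` are also present; an optional ``exclusion_plane`` mask is
    honoured when ``options["use_exclusion_plane"]`` is set.

    Protocol order: (1) dissect the stria (amygdala seed, frontal-horn
    waypoint(s), BNST termination, and — unless disabled — the pulvinar as an
    exclusion mask, since the stria terminalis does not traverse the pulvinar
    and amygdala-seeded samples that stray onto the colliculo-pulvinar
    pathway must not enter the stria streamline); (2) dissect SC -> amygdala
    (pulvinar waypoint optional); (3) repeat the SC -> amygdala dissection
    with the binarised *unthresholded* stria visitation map as an exclusion
    mask (trimmed of the pathway's own ROIs, which the stria necessarily
    covers at its amygdala seed); (4) threshold everything at 10%;
    (5) optionally add the reversed run and compute the bidirectional
    overlap.
    """
    options = {
        "use_pulvinar_waypoint": True,
        "use_exclusion_plane": False,
        "stria_exclude_pulvinar": True,
        "compute_overlap": False,
        "threshold_fraction": 0.10,
        **(options or {}),
    }
    sc = masks["sc"].with_role("seed")
    pulv = masks["pulvinar"].with_role("waypoint")
    amyg_wp = masks["amygdala"].with_role("waypoint")
    amyg_term = masks["amygdala"].with_role("termination")
    diagnostics: dict = {}

    base_excl = []
    if options["use_exclusion_plane"] and "exclusion_plane" in masks:
        base_excl.append(masks["exclusion_plane"].with_role("exclusion"))

    # (1) stria terminalis
    stria_map = None
    if "bnst" in masks and masks.get("stria_waypoints"):
        stria_map = track(
            field,
            seed=masks["amygdala"].with_role("seed"),
            waypoints=[m.with_role("waypoint") for m in masks["stria_waypoints"]],
            termination=masks["bnst"].with_role("termination"),
            exclusions=[masks["pulvinar"].with_role("exclusion")] if options["stria_exclude_pulvinar"] else [],
            config=config,
        )
        diagnostics["stria_n_retained"] = stria_map.n_retained

    # (2) SC -> amygdala, no stria exclusion
    waypoints = ([pulv] if options["use_pulvinar_waypoint"] else []) + [amyg_wp]
    plain_map = track(field, seed=sc, waypoints=waypoints, termination=amyg_term,
                      exclusions=base_excl, config=config)
    diagnostics["sc_amygdala_n_retained"] = plain_map.n_retained

    # (3) re-dissect with the unthresholded stria streamline as exclusion
    excl_map = None
    stria_skipped = False
    if stria_map is not None and stria_map.n_retained > 0:
        stria_excl_grid = stria_map.binarized().copy()
        for roi in (sc, pulv, amyg_wp):
            stria_excl_grid &= ~roi.grid
        excl_map = track(
            field, seed=sc, waypoints=waypoints, termination=amyg_term,
            exclusions=base_excl + [ROIMask(stria_excl_grid, role="exclusion", name="stria_unthresholded")],
            config=config,
        )
        diagnostics["sc_amygdala_excl_n_retained"] = excl_map.n_retained
    elif stria_map is not None:
        warnings.warn("stria dissection retained zero streamlines; exclusion step skipped")
        stria_skipped = True
    diagnostics["stria_exclusion_skipped"] = stria_skipped

    # (4) threshold at 10%
    frac = options["threshold_fraction"]
    stria_mask = threshold_map(stria_map, frac) if stria_map is not None and stria_map.n_retained else None
    final_map = excl_map if excl_map is not None and excl_map.n_retained else plain_map
    sc_amyg_mask = threshold_map(final_map, frac) if final_map.n_retained else None
    diagnostics["sc_amygdala_noexcl_mask"] = threshold_map(plain_map, frac) if plain_map.n_retained else None
    diagnostics["plain_map"] = plain_map
    diagnostics["excl_map"] = excl_map
    diagnostics["stria_map"] = stria_map

    # (5) bidirectional overlap
    overlap = None
    continuous = False
    if options["compute_overlap"] and final_map.n_retained:
        reverse = track(field, seed=masks["amygdala"].with_role("seed"),
                        waypoints=([pulv] if options["use_pulvinar_waypoint"] else []) + [masks["sc"].with_role("waypoint")],
                        termination=masks["sc"].with_role("termination"),
                        exclusions=base_excl, config=config)
        diagnostics["reverse_n_retained"] = reverse.n_retained
        overlap, continuous = overlap_bidirectional(plain_map, reverse, masks["sc"], masks["amygdala"])
        diagnostics["reverse_map"] = reverse

    return DissectionResult(sc_amyg_mask, stria_mask, overlap, continuous, diagnostics)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between binary volumes."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float(np.sum(a & b)) / float(denom) if denom else 0.0
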