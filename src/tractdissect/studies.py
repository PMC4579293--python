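"""Canonical study phantoms and acquisition schemes.

These builders pin down the synthetic study conditions used throughout the
analysis scripts, tests and acceptance run: an arcing three-ROI bundle
(superior colliculus -> dorsolateral pulvinar pole -> over a signal-void
temporal horn -> lateral amygdala), optionally joined by a second
"stria terminalis" bundle that runs adjacent to the pathway above the void
before diverging medially toward a frontal-horn waypoint and a BNST
termination region.  Geometry is expressed in fractions of the grid extent
so that reduced-size phantoms keep the same topology.
"""

from __future__ import annotations

import math

import numpy as np

from .phantom import BundleSpec, PhantomSpec, RegionSpec
from .scheme import AcquisitionScheme, make_scheme

# control points in fractions of the grid extent (x, y, z); y is coronal
_MAIN_FRACS = [
    (0.50, 0.17, 0.35),   # superior colliculus
    (0.50, 0.30, 0.65),   # dorsolateral pulvinar pole
    (0.62, 0.42, 0.50),   # descending laterally
    (0.68, 0.53, 0.45),   # above the temporal horn
    (0.68, 0.67, 0.42),
    (0.68, 0.80, 0.33),   # lateral amygdala
]
_STRIA_FRACS = [
    (0.577, 0.79, 0.397),  # emerges from the medial-superior amygdala
    (0.53, 0.64, 0.52),
    (0.628, 0.545, 0.512),  # runs tangent to the pathway above the horn
    (0.55, 0.44, 0.54),
    (0.50, 0.38, 0.53),
    (0.35, 0.30, 0.55),    # subjacent to the frontal horn
    (0.33, 0.22, 0.50),    # bed nucleus of the stria terminalis
]
_HORN_CENTER = (0.68, 0.60, 0.24)
_HORN_SEMI = (0.09, 0.11, 0.065)  # fractions of extent


def _mm(frac, extent):
    return tuple(f * e for f, e in zip(frac, extent))


def build_pathway_spec(shape=(40, 60, 40), with_stria: bool = False, snr: float = math.inf,
                       seed: int = 0, bundle_radius: float = 2.5, stria_radius: float = 2.0,
                       stick_fraction: float = 0.7, diffusivity: float = 1.7e-3) -> PhantomSpec:
    """The study phantom: arcing pathway, temporal-horn void, dissection ROIs."""
    shape = tuple(int(s) for s in shape)
    extent = tuple((s - 1) * 1.0 for s in shape)
    main = BundleSpec(
        centerline=np.array([_mm(f, extent) for f in _MAIN_FRACS]),
        radius=bundle_radius, stick_fraction=stick_fraction, diffusivity=diffusivity,
    )
    bundles = {"sc_amygdala": main}
    rois = [
        RegionSpec("sc", "sphere", _mm(_MAIN_FRACS[0], extent), 2.5, role="seed"),
        RegionSpec("pulvinar", "sphere", _mm(_MAIN_FRACS[1], extent), 3.5, role="waypoint"),
        RegionSpec("amygdala", "ellipsoid", _mm(_MAIN_FRACS[-1], extent), (5.5, 3.0, 4.0), role="termination"),
    ]
    if with_stria:
        bundles["stria"] = BundleSpec(
            centerline=np.array([_mm(f, extent) for f in _STRIA_FRACS]),
            radius=stria_radius, stick_fraction=stick_fraction, diffusivity=diffusivity,
        )
        rois += [
            RegionSpec("stria_proximal", "sphere", _mm(_STRIA_FRACS[1], extent), 3.0, role="waypoint"),
            RegionSpec("stria_frontal", "sphere", _mm(_STRIA_FRACS[-2], extent), 3.0, role="waypoint"),
            RegionSpec("bnst", "sphere", _mm(_STRIA_FRACS[-1], extent), 2.5, role="termination"),
        ]
    voids = [RegionSpec("temporal_horn", "ellipsoid", _mm(_HORN_CENTER, extent),
                        _mm(_HORN_SEMI, extent))]
    return PhantomSpec(
        grid_shape=shape, voxel_size=(1.0, 1.0, 1.0), bundles=bundles,
        void_regions=voids, roi_specs=rois, snr=snr, rng_seed=seed,
    )


def study_schemes(seed: int = 1) -> dict[str, AcquisitionScheme]:
    """The three acquisition protocols emulated by the phantom module."""
    return {
        "human_group1": make_scheme(32, 800.0, 4, rng_seed=seed),
        "human_group2": make_scheme(61, 2000.0, 4, rng_seed=seed + 1),
        "monkey": make_scheme(60, 1000.0, 11, rng_seed=seed + 2),
    }


def monkey_scheme(seed: int = 3) -> AcquisitionScheme:
    """11 x b=0 plus 60 directions at b=1000 — the 1 mm protocol."""
    return make_scheme(60, 1000.0, 11, rng_seed=seed)

def pathway_masks(gt) -> dict:
    """Assemble the dissection-protocol mask dictionary from a ground truth."""
    masks = {"sc": gt.rois["sc"], "pulvinar": gt.rois["pulvinar"], "amygdala": gt.rois["amygdala"]}
    if "bnst" in gt.rois:
        masks["bnst"] = gt.rois["bnst"]
        masks["stria_waypoints"] = [gt.rois["stria_proximal"], gt.rois["stria_frontal"]]
    return masks


def run_pathway_study(shape=(40, 60, 40), with_stria: bool = False, snr: float = math.inf,
                      samples_per_seed_voxel: int = 500, K: int = 50,
                      fit_seed: int = 11, track_seed: int = 13, scheme_seed: int = 3,
                      options: dict | None = None):
    """Simulate, fit and dissect one study phantom end to end.

    Returns ``(spec, gt, field, DissectionResult)`` — the full pipeline at the
    study's standard settings, shared by the analysis drivers and the
    acceptance script.
    """
    from .dissection import dissect_pathway
    from .modelfit import fit_volume
    from .phantom import brain_mask, simulate_phantom
    from .tracker import TrackerConfig

    spec = build_pathway_spec(shape, with_stria=with_stria, snr=snr)
    dwv, gt = simulate_phantom(spec, monkey_scheme(scheme_seed))
    field = fit_volume(dwv, brain_mask(spec, gt), K=K, rng_seed=fit_seed)
    cfg = TrackerConfig(samples_per_seed_voxel=samples_per_seed_voxel, rng_seed=track_seed)
    res = dissect_pathway(field, pathway_masks(gt), cfg, options=options)
    return spec, gt, field, res


def simulate_cog_cohort(n_subjects: int = 12, n_slices: int = 8, jitter_mm: float = 1.0,
                        offset_mm: float = 5.4, rng_seed: int = 0):
    """Per-slice CoG profiles for a synthetic cohort of subjects.

    Emulates the variability analysis: each subject's pathway CoG is the true
    trajectory plus independent N(0, jitter) in-plane displacements, in both
    hemispheres; a second streamline runs ``offset_mm`` medial to the first.
    Returns ``(pathway_profiles, stria_profiles)`` lists of CoGProfile.
    """
    from .stats import CoGProfile

    rng = np.random.default_rng(rng_seed)
    slices = np.arange(n_slices)
    truth_x = np.linspace(26.0, 27.0, n_slices)
    truth_z = np.linspace(17.0, 16.0, n_slices)
    pathway, stria = [], []
    for s in range(n_subjects):
        for hemi in ("L", "R"):
            pathway.append(CoGProfile(
                slices,
                truth_x + rng.normal(0.0, jitter_mm, n_slices),
                truth_z + rng.normal(0.0, jitter_mm, n_slices),
                subject=f"s{s:02d}", hemisphere=hemi, streamline="sc_amygdala",
            ))
            stria.append(CoGProfile(
                slices,
                truth_x - offset_mm + rng.normal(0.0, jitter_mm, n_slices),
                truth_z + rng.normal(0.0, jitter_mm, n_slices),
                subject=f"s{s:02d}", hemisphere=hemi, streamline="stria",
            ))
    return pathway, stria
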