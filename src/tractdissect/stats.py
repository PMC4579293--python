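"""Tract-profile statistics: per-slice centers of gravity, cross-subject
variability tables, and between-streamline offset ANOVA.

The spatial unit of analysis is the in-plane centroid ("center of gravity",
CoG) of a binary streamline mask within one coronal (y) slice, expressed in
world millimetres.  Cross-subject variability is summarised as the per-slice
standard deviation of the CoG across subjects (per hemisphere, per axis),
with the mean and SD of those per-slice values appended — the layout of the
classic tract-variability table.  Two streamlines are compared with a
two-factor (streamline x participant) ANOVA on per-slice CoG values, testing
the streamline effect against the streamline-by-participant interaction,
which for two streamlines is the paired design with df = (1, n_subjects-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CoGProfile:
    """Per-coronal-slice in-plane centroid of a streamline mask (world mm)."""

    slice_indices: np.ndarray
    x_mm: np.ndarray
    z_mm: np.ndarray
    subject: str = ""
    hemisphere: str = ""
    streamline: str = ""

    def __post_init__(self):
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        if not len(self.slice_indices) == len(self.x_mm) == len(self.z_mm):
            raise ValueError("profile arrays must align")

    def axis_values(self, axis: str) -> np.ndarray:
        if axis == "x":
            return self.x_mm
        if axis == "z":
            return self.z_mm
        raise ValueError("axis must be 'x' or 'z'")


@dataclass
class VariabilityTable:
    """Per-slice cross-subject SDs with Mean/SD summary rows."""

    table: pd.DataFrame
    unit: str = "mm"


@dataclass
class OffsetComparison:
    """Streamline-effect test and mean offset between two tract profiles."""

    axis: str
    mean_offset: float
    se_offset: float
    F: float
    df: tuple
    p_value: float
    degenerate: bool = False


def cog_profile(mask, slice_range, affine, weights: np.ndarray | None = None, **labels) -> CoGProfile:
    """Per-slice centroid of mask-voxel centers mapped through ``affine``.

    ``mask`` is a StreamlineMask or boolean volume; ``slice_range`` an
    iterable of coronal (second-axis) indices, each of which must contain at
    least one mask voxel.  ``weights`` optionally weights voxels by a count
    volume (the default is the unweighted binary centroid).
    """
    grid = mask.grid if hasattr(mask, "grid") else np.asarray(mask, bool)
    affine = np.asarray(affine, dtype=float)
    slices = [int(y) for y in slice_range]
    xs, zs = [], []
    for y in slices:
        ii, kk = np.nonzero(grid[:, y, :])
        if ii.size == 0:
            raise ValueError(f"slice {y} contains no streamline voxels")
        w = weights[ii, y, kk] if weights is not None else np.ones(ii.size)
        ci = float(np.average(ii, weights=w))
        ck = float(np.average(kk, weights=w))
        world = affine @ np.array([ci, float(y), ck, 1.0])
        xs.append(world[0])
        zs.append(world[2])
    return CoGProfile(np.array(slices), np.array(xs), np.array(zs), **labels)


def variability_table(profiles, slices, voxel_size_mm: float | None = None) -> VariabilityTable:
    """Across-subject SD (ddof=1) of CoG x and z per slice and hemisphere.

    ``profiles`` is an iterable of CoGProfile with ``subject`` and
    ``hemisphere`` labels; every profile must cover ``slices``.  Columns are
    per-hemisphere SDs plus cross-hemisphere means; the final rows are the
    column means and the SD of the per-slice values.  If ``voxel_size_mm``
    is given, values are reported in isotropic-voxel units instead of mm.
    """
    slices = [int(y) for y in slices]
    rows = []
    for p in profiles:
        lookup = {int(s): i for i, s in enumerate(p.slice_indices)}
        for y in slices:
            if y not in lookup:
                raise ValueError(f"profile {p.subject}/{p.hemisphere} misses slice {y}")
            i = lookup[y]
            rows.append({"subject": p.subject, "hemisphere": p.hemisphere, "slice": y,
                         "x": p.x_mm[i], "z": p.z_mm[i]})
    long = pd.DataFrame(rows)
    if long["subject"].nunique() < 2:
        raise ValueError("variability table needs at least two subjects")
    hemis = sorted(long["hemisphere"].unique())
    out = pd.DataFrame(index=pd.Index(slices, name="slice"))
    for h in hemis:
        sub = long[long["hemisphere"] == h]
        sd = sub.groupby("slice")[["x", "z"]].std(ddof=1)
        out[f"{h}_x_sd"] = sd["x"]
        out[f"{h}_z_sd"] = sd["z"]
    out["mean_x_sd"] = out[[f"{h}_x_sd" for h in hemis]].mean(axis=1)
    out["mean_z_sd"] = out[[f"{h}_z_sd" for h in hemis]].mean(axis=1)
    if voxel_size_mm is not None:
        out = out / float(voxel_size_mm)
    summary = pd.DataFrame([out.mean(axis=0), out.std(axis=0, ddof=1)], index=["Mean", "SD"])
    table = pd.concat([out, summary])
    return VariabilityTable(table, unit="voxel" if voxel_size_mm is not None else "mm")


def _two_factor_anova(values: np.ndarray):
    """Streamline x participant ANOVA on a (2, n_subjects, n_slices) array.

    Returns (F, df, p, degenerate) for the streamline effect, tested against
    the streamline-by-participant interaction mean square.
    """
    a, n, m = values.shape
    grand = values.mean()
    mean_s = values.mean(axis=(1, 2))          # per streamline
    mean_p = values.mean(axis=(0, 2))          # per participant
    mean_sp = values.mean(axis=2)              # per cell
    ss_s = n * m * np.sum((mean_s - grand) ** 2)
    ss_int = m * np.sum((mean_sp - mean_s[:, None] - mean_p[None, :] + grand) ** 2)
    df_s = a - 1
    df_int = (a - 1) * (n - 1)
    ms_int = ss_int / df_int
    # guard degenerate cases on a scale relative to the data's total variation
    eps = 1e-12 * max(float(np.sum((values - grand) ** 2)), 1.0)
    if ss_s <= eps:
        return 0.0, (df_s, df_int), 1.0, False
    if ms_int <= eps:
        return float("inf"), (df_s, df_int), 0.0, True
    F = (ss_s / df_s) / ms_int
    return float(F), (df_s, df_int), float(sps.f.sf(F, df_s, df_int)), False


def compare_offsets(profiles_a, profiles_b, axis: str) -> OffsetComparison:
    """Compare the CoG of two streamlines along one axis ('x' or 'z').

    ``profiles_a``/``profiles_b``: one CoGProfile per subject for each
    streamline, with matching subjects and slices.  Reports the streamline
    effect F(1, n-1) against the streamline-by-participant interaction and
    the mean A-B offset with its standard error across subjects.
    """
    pa = {p.subject: p for p in profiles_a}
    pb = {p.subject: p for p in profiles_b}
    if set(pa) != set(pb):
        raise ValueError("subject sets differ between the two streamlines")
    subjects = sorted(pa)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    slices = tuple(pa[subjects[0]].slice_indices.tolist())
    for s in subjects:
        if tuple(pa[s].slice_indices.tolist()) != slices or tuple(pb[s].slice_indices.tolist()) != slices:
            raise ValueError("slice sets differ across subjects or streamlines")
    va = np.stack([pa[s].axis_values(axis) for s in subjects])
    vb = np.stack([pb[s].axis_values(axis) for s in subjects])
    values = np.stack([va, vb])                     # (2, n, m)
    F, df, p, degenerate = _two_factor_anova(values)
    diff = va.mean(axis=1) - vb.mean(axis=1)        # per-subject A-B offset
    mean_offset = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else float("nan")
    return OffsetComparison(axis, mean_offset, se, F, df, p, degenerate)
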