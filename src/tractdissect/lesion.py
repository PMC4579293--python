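"""Lesion-streamline intersection analysis.

Decides whether a focal lesion would have interrupted a tract: in every
coronal slice where the streamline is present, the fraction of its voxels
covered by the lesion is computed; the tract counts as interrupted when any
slice's coverage reaches the threshold (default 1.0, i.e. the lesion
transects the tract's entire cross-section somewhere along its course).
The coverage criterion is this package's operational definition — published
lesion analyses of this kind judged interruption visually — and it is
surfaced in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd


@dataclass
class LesionReport:
    """Interruption verdict with per-slice coverage diagnostics."""

    interrupted: bool
    overlap_voxels: int
    coverage: pd.Series              # per-slice fraction of streamline inside lesion
    coverage_threshold: float

    def to_dict(self) -> dict:
        return {
            "interrupted": bool(self.interrupted),
            "overlap_voxels": int(self.overlap_voxels),
            "coverage_threshold": float(self.coverage_threshold),
            "max_slice_coverage": float(self.coverage.max()) if len(self.coverage) else 0.0,
            "per_slice_coverage": {int(k): float(v) for k, v in self.coverage.items()},
        }


def intersect_lesion(streamline, lesion, coverage_threshold: float = 1.0, axis: int = 1) -> LesionReport:
    """Per-slice lesion coverage of a streamline along its principal axis.

    ``axis`` defaults to the coronal (y) axis.  Coverage in a slice is
    |streamline ∩ lesion ∩ slice| / |streamline ∩ slice|, over slices where
    the streamline is present; ``interrupted`` iff any coverage reaches the
    threshold.
    """
    s = streamline.grid if hasattr(streamline, "grid") else np.asarray(streamline, bool)
    l = lesion.grid if hasattr(lesion, "grid") else np.asarray(lesion, bool)
    if s.shape != l.shape:
        raise ValueError("streamline and lesion must share a grid")
    if not s.any():
        raise ValueError("empty streamline mask")
    other = tuple(i for i in range(3) if i != axis)
    s_per = s.sum(axis=other)
    both_per = (s & l).sum(axis=other)
    present = np.nonzero(s_per)[0]
    cov = pd.Series(both_per[present] / s_per[present], index=present, dtype=float)
    interrupted = bool((cov >= coverage_threshold - 1e-12).any())
    return LesionReport(interrupted, int((s & l).sum()), cov, float(coverage_threshold))
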