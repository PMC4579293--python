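"""Build the study phantoms and record their geometry.

Simulates the two canonical synthetic acquisitions — the three-ROI arcing
pathway phantom and the two-bundle crossing phantom with the decoy "stria
terminalis" — under the 60-direction b=1000 protocol, writes the volumes to
scratch/phantoms/ (NIfTI + FSL bvals/bvecs) and a geometry summary to
results/phantom_geometry.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import tractdissect as td
from tractdissect import io as tio

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "phantoms"
RESULTS = ROOT / "results"


def main():
    scheme = td.monkey_scheme()
    rows = []
    for name, with_stria in (("single_bundle", False), ("crossing", True)):
        spec = td.build_pathway_spec((40, 60, 40), with_stria=with_stria)
        dwv, gt = td.simulate_phantom(spec, scheme)
        out = SCRATCH / name
        tio.save_dwi(dwv, out)
        tio.save_mask(td.brain_mask(spec, gt), out / "brain_mask.nii.gz")
        for roi_name, roi in gt.rois.items():
            tio.save_mask(roi, out / f"roi_{roi_name}.nii.gz")
        for b_name, occ in gt.occupancy.items():
            tio.save_mask(occ, out / f"truth_{b_name}.nii.gz")
        row = {
            "phantom": name,
            "n_volumes": scheme.n_volumes,
            "pathway_voxels": int(gt.occupancy["sc_amygdala"].sum()),
            "void_voxels": int(gt.void.sum()),
        }
        if with_stria:
            row["stria_voxels"] = int(gt.occupancy["stria"].sum())
            row["shared_voxels"] = int((gt.occupancy["stria"] & gt.occupancy["sc_amygdala"]).sum())
        for roi_name, roi in gt.rois.items():
            row[f"roi_{roi_name}_voxels"] = roi.n_voxels
        rows.append(row)
        print(f"{name}: pathway {row['pathway_voxels']} voxels, "
              f"{'stria %d voxels (%d shared), ' % (row['stria_voxels'], row['shared_voxels']) if with_stria else ''}"
              f"void {row['void_voxels']} voxels -> {out}")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "phantom_geometry.csv", index=False)
    print(f"wrote {RESULTS / 'phantom_geometry.csv'}")


if __name__ == "__main__":
    main()
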