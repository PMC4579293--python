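"""Reading and writing the pipeline's on-disk artifacts.

Volumes travel as NIfTI-1 (via nibabel) with an RAS affine of
``diag(voxel_size)``; acquisition schemes as FSL-dialect ``bvals``/``bvecs``
text files; orientation fields as a 5D NIfTI pair plus a JSON sidecar;
visitation maps as int32 NIfTI plus a JSON sidecar; masks as uint8 NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .masks import ROIMask
from .modelfit import OrientationField
from .phantom import DWVolume
from .scheme import AcquisitionScheme, load_fsl, save_fsl
from .tracker import VisitationMap


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_dwi(dwv: DWVolume, out_dir, stem: str = "dwi") -> None:
    """Write <stem>.nii.gz plus FSL bvals/bvecs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(dwv.data.astype(np.float32), _affine(dwv.voxel_size))
    nib.save(img, out / f"{stem}.nii.gz")
    save_fsl(dwv.scheme, out / "bvals", out / "bvecs")


def load_dwi(dwi_path, bvals_path, bvecs_path) -> DWVolume:
    img = nib.load(str(dwi_path))
    scheme = load_fsl(bvals_path, bvecs_path)
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DWVolume(np.asarray(img.dataobj, dtype=np.float64), scheme, vs)


def save_mask(mask, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    grid = mask.grid if hasattr(mask, "grid") else np.asarray(mask, bool)
    nib.save(nib.Nifti1Image(grid.astype(np.uint8), _affine(voxel_size)), str(path))


def load_mask(path, role: str = "waypoint", name: str = "") -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.dataobj) > 0, role=role, name=name or Path(path).stem)


def save_field(field: OrientationField, out_dir, stem: str = "field") -> None:
    """Orientation samples and fractions as 5D NIfTI + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.voxel_size)
    nib.save(nib.Nifti1Image(field.orientations.astype(np.float32), aff), out / f"{stem}_orientations.nii.gz")
    nib.save(nib.Nifti1Image(field.fractions.astype(np.float32), aff), out / f"{stem}_fractions.nii.gz")
    nib.save(nib.Nifti1Image(field.s0.astype(np.float32), aff), out / f"{stem}_s0.nii.gz")
    nib.save(nib.Nifti1Image(field.d.astype(np.float32), aff), out / f"{stem}_d.nii.gz")
    nib.save(nib.Nifti1Image(field.brain_mask.astype(np.uint8), aff), out / f"{stem}_mask.nii.gz")
    (out / f"{stem}.json").write_text(json.dumps({"K": field.K, "voxel_size": list(field.voxel_size)}))


def load_field(out_dir, stem: str = "field") -> OrientationField:
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}.json").read_text())
    ors = np.asarray(nib.load(str(out / f"{stem}_orientations.nii.gz")).dataobj, dtype=np.float32)
    frs = np.asarray(nib.load(str(out / f"{stem}_fractions.nii.gz")).dataobj, dtype=np.float32)
    s0 = np.asarray(nib.load(str(out / f"{stem}_s0.nii.gz")).dataobj, dtype=np.float64)
    d = np.asarray(nib.load(str(out / f"{stem}_d.nii.gz")).dataobj, dtype=np.float64)
    mask = np.asarray(nib.load(str(out / f"{stem}_mask.nii.gz")).dataobj) > 0
    return OrientationField(ors, frs, s0, d, mask, int(meta["K"]), tuple(meta["voxel_size"]))


def save_visitation(vmap: VisitationMap, path, sidecar_path=None) -> None:
    nib.save(nib.Nifti1Image(vmap.counts.astype(np.int32), _affine(vmap.voxel_size)), str(path))
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({
        "n_seed_samples": vmap.n_seed_samples,
        "n_retained": vmap.n_retained,
        "config": vmap.config,
    }, indent=2))


def load_visitation(path, sidecar_path=None) -> VisitationMap:
    img = nib.load(str(path))
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(path)).with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    return VisitationMap(np.asarray(img.dataobj, dtype=np.int32), meta["n_seed_samples"],
                         meta["n_retained"], meta.get("config", {}), vs)
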