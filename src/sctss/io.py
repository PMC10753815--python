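"""NIfTI volume I/O for DWI/ADC pairs and masks."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from sctss.types import VolumePair


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume_pair(vol: VolumePair, out_dir, case_id: Optional[str] = None) -> dict:
    """Write dwi/adc/brain_mask (and lesion_mask if present) as NIfTI files
    plus a JSON sidecar with the processing metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_id = case_id or vol.meta.get("case_id", "case")
    affine = _affine(vol.spacing)
    paths = {}
    arrays = {
        "dwi": vol.dwi.astype(np.float32),
        "adc": vol.adc.astype(np.float32),
        "brain_mask": vol.brain_mask.astype(np.uint8),
    }
    if vol.lesion_mask is not None:
        arrays["lesion_mask"] = vol.lesion_mask.astype(np.uint8)
    for name, arr in arrays.items():
        p = out_dir / f"{case_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), p)
        paths[name] = p
    sidecar = out_dir / f"{case_id}_meta.json"
    sidecar.write_text(json.dumps(vol.meta, indent=1, sort_keys=True, default=str))
    paths["meta"] = sidecar
    return paths


def load_volume_pair(out_dir, case_id: str) -> VolumePair:
    out_dir = Path(out_dir)

    def _load(name):
        return nib.load(out_dir / f"{case_id}_{name}.nii.gz")

    dwi_img = _load("dwi")
    spacing = tuple(float(z) for z in dwi_img.header.get_zooms()[:3])
    lesion_path = out_dir / f"{case_id}_lesion_mask.nii.gz"
    meta_path = out_dir / f"{case_id}_meta.json"
    return VolumePair(
        dwi=np.asarray(dwi_img.dataobj, dtype=float),
        adc=np.asarray(_load("adc").dataobj, dtype=float),
        spacing=spacing,
        brain_mask=np.asarray(_load("brain_mask").dataobj) > 0,
        lesion_mask=(
            np.asarray(nib.load(lesion_path).dataobj) > 0 if lesion_path.exists() else None
        ),
        meta=json.loads(meta_path.read_text()) if meta_path.exists() else {},
    )
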