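"""NIfTI and bval I/O helpers built on nibabel."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMap
from .scheme import BValueScheme, read_bval

__all__ = ["load_dwi", "load_mask", "save_parameter_maps"]


def load_dwi(nii_path: str | Path, bval_path: str | Path,
             n_directions: int = 30) -> tuple[np.ndarray, BValueScheme]:
    """Load a 4D DWI volume and its FSL-style bval file."""
    vol = np.asarray(nib.load(str(nii_path)).dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {vol.shape}")
    scheme = BValueScheme(tuple(read_bval(bval_path)), n_directions)
    if vol.shape[-1] != scheme.n_b:
        raise ValueError("volume and bval file disagree on the shell count")
    return vol, scheme


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary VOI mask."""
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_parameter_maps(maps: list[ParameterMap], out_dir: str | Path,
                        voxel_size_mm: float = 2.2) -> list[Path]:
    """Write one NIfTI per parameter plus the shared RSS map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    written = []
    for pmap in maps:
        path = out_dir / f"{pmap.name}.nii.gz"
        nib.save(nib.Nifti1Image(pmap.data.astype(np.float32), affine), path)
        written.append(path)
    if maps:
        path = out_dir / f"{maps[0].model}_rss.nii.gz"
        nib.save(nib.Nifti1Image(maps[0].rss.astype(np.float32), affine),
                 path)
        written.append(path)
    return written
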