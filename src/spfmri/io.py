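"""NIfTI readers/writers and run-configuration plumbing.

Coordinates are 0-based voxel indices internally; the NIfTI affine is
carried through untouched (no resampling anywhere).  Masked/invalid
voxels are serialized as NaN and restored as masked.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from spfmri import __version__
from spfmri.dwi_fitting import ParametricMap
from spfmri.signal_models import BValueScheme

__all__ = ["read_dwi", "write_dwi", "write_map", "read_map", "write_run_config"]

log = logging.getLogger(__name__)


def read_dwi(path_nifti, path_bval):
    """Read a 4D DWI NIfTI plus FSL-style whitespace-separated .bval file.

    Returns (volume, scheme, affine).  If the b-values are unsorted the
    volume is re-ordered together with the scheme (logged).
    """
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    bvals = np.loadtxt(str(path_bval), ndmin=1).ravel()
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"bval count {bvals.size} does not match volume count {data.shape[3]}"
        )
    order = np.argsort(bvals, kind="stable")
    if not np.array_equal(order, np.arange(bvals.size)):
        log.info("b-values unsorted: re-ordering volumes to match sorted scheme")
        bvals = bvals[order]
        data = data[..., order]
    return data, BValueScheme(tuple(bvals)), img.affine


def write_dwi(volume, scheme: BValueScheme, path_nifti, path_bval, affine=None):
    """Write a 4D DWI volume and its .bval sidecar."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path_nifti))
    with open(path_bval, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")


def write_map(pmap: ParametricMap, path, affine=None) -> Path:
    """Write a ParametricMap as float32 NIfTI (masked voxels -> NaN) with
    a JSON sidecar recording parameter, method and configuration."""
    path = Path(path)
    if affine is None:
        affine = np.diag([*pmap.voxel_size, 1.0])
    values = np.where(pmap.mask, pmap.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(values, affine)
    img.header["descrip"] = pmap.parameter_name.encode()[:79]
    img.header.set_zooms(pmap.voxel_size)
    nib.save(img, str(path))
    sidecar = {
        "parameter": pmap.parameter_name,
        "version": __version__,
        **pmap.meta,
    }
    sidecar["config_hash"] = hashlib.sha256(
        json.dumps(sidecar, sort_keys=True).encode()
    ).hexdigest()[:16]
    side_path = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    side_path = side_path.parent / (side_path.name + ".json")
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return side_path


def read_map(path) -> ParametricMap:
    """Read a map written by :func:`write_map` (NaN voxels -> masked)."""
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    mask = np.isfinite(values)
    side_path = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    side_path = side_path.parent / (side_path.name + ".json")
    meta = {}
    name = str(img.header["descrip"].astype(str)) or "unknown"
    if side_path.exists():
        with open(side_path) as fh:
            meta = json.load(fh)
        name = meta.get("parameter", name)
    zooms = img.header.get_zooms()[:3]
    return ParametricMap(
        values=values, mask=mask,
        voxel_size=tuple(float(z) for z in zooms),
        parameter_name=name,
        meta={k: v for k, v in meta.items() if k not in ("parameter", "version")},
    )


def write_run_config(config: dict, out_dir) -> Path:
    """Persist the resolved run configuration next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    with open(path, "w") as fh:
        json.dump({"version": __version__, **config}, fh, indent=2, default=str)
    return path
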