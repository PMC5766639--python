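"""Hot-spot ROI extraction: locate the round region with extreme mean
value on a parametric map within a tumor mask.

Discs are 2D in-plane (thick, gapped slices make 3D spheres anisotropic
and slices effectively independent); the disc honors the in-plane voxel
size.  Avoidance of necrosis/cysts/vessels is the upstream mask's
responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from spfmri.dwi_fitting import ParametricMap

__all__ = ["HotspotROI", "extract_hotspot", "propagate_roi", "disc_offsets"]

log = logging.getLogger(__name__)


@dataclass
class HotspotROI:
    """A circular in-plane ROI located by the hot-spot method."""

    center: tuple[int, int, int]  # 0-based voxel coordinates, x/y/z
    radius_mm: float
    mean_value: float
    mode: str  # 'max' or 'min'
    n_voxels: int
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    def to_dict(self) -> dict:
        return {
            "center": [int(c) for c in self.center],
            "radius_mm": float(self.radius_mm),
            "mean_value": float(self.mean_value),
            "mode": self.mode,
            "n_voxels": int(self.n_voxels),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "HotspotROI":
        return cls(
            center=tuple(d["center"]),
            radius_mm=d["radius_mm"],
            mean_value=d["mean_value"],
            mode=d["mode"],
            n_voxels=d["n_voxels"],
        )


def disc_offsets(
    radius_mm: float, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """In-plane (dx, dy) offsets of voxels whose centers lie within
    radius_mm of the disc center, honoring anisotropic in-plane spacing."""
    vx, vy = voxel_size[0], voxel_size[1]
    nx = int(np.floor(radius_mm / vx))
    ny = int(np.floor(radius_mm / vy))
    dx, dy = np.meshgrid(np.arange(-nx, nx + 1), np.arange(-ny, ny + 1), indexing="ij")
    inside = (dx * vx) ** 2 + (dy * vy) ** 2 <= radius_mm**2 + 1e-9
    return np.stack([dx[inside], dy[inside]], axis=1)


def _disc_kernel(radius_mm, voxel_size):
    off = disc_offsets(radius_mm, voxel_size)
    nx = int(np.abs(off[:, 0]).max()) if len(off) else 0
    ny = int(np.abs(off[:, 1]).max()) if len(off) else 0
    kernel = np.zeros((2 * nx + 1, 2 * ny + 1), dtype=bool)
    kernel[off[:, 0] + nx, off[:, 1] + ny] = True
    return kernel


def extract_hotspot(
    pmap: ParametricMap,
    mask: np.ndarray,
    radius_mm: float = 5.0,
    mode: str = "max",
) -> HotspotROI:
    """Find the in-plane disc (fully inside the mask) whose mean map
    value is extreme.

    Every voxel whose disc lies entirely within the mask is a candidate
    center; the disc mean is evaluated there and the center maximizing
    (mode='max') or minimizing (mode='min') that mean is returned.  Ties
    break to the first center in row-major (x, y, z) scan order.  If no
    disc fits, the radius shrinks by one in-plane voxel step at a time
    (logged) down to a single voxel.
    """
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.shape:
        raise ValueError("map and mask must share one grid")
    if not mask.any():
        raise ValueError("mask is empty")

    usable = mask & pmap.mask
    if not usable.any():
        raise ValueError("mask contains no valid map voxels")
    vox = pmap.voxel_size
    step = min(vox[0], vox[1])

    radius = float(radius_mm)
    while True:
        kernel = _disc_kernel(radius, vox)
        result = _best_center(pmap.values, usable, kernel, mode)
        if result is not None:
            center, mean, n = result
            if radius < radius_mm:
                log.warning(
                    "no disc of radius %.3g mm fit inside the mask; shrunk to %.3g mm",
                    radius_mm, radius,
                )
            off = disc_offsets(radius, vox)
            xs = center[0] + off[:, 0]
            ys = center[1] + off[:, 1]
            zs = np.full(len(off), center[2])
            return HotspotROI(
                center=center,
                radius_mm=radius,
                mean_value=mean,
                mode=mode,
                n_voxels=n,
                voxel_indices=(xs, ys, zs),
            )
        radius -= step
        if radius <= 0:
            # single-voxel disc always fits somewhere in a non-empty mask
            radius = step * 0.5

def _best_center(values, usable, kernel, mode):
    filled = np.where(usable, values, 0.0)
    n_kernel = int(kernel.sum())
    best = None
    for z in range(values.shape[2]):
        m = usable[:, :, z]
        if not m.any():
            continue
        # centers whose entire disc is inside the usable mask
        ok = ndimage.binary_erosion(m, structure=kernel, border_value=0)
        if not ok.any():
            continue
        sums = ndimage.correlate(filled[:, :, z], kernel.astype(float), mode="constant")
        means = sums / n_kernel
        cand = np.where(ok, means, np.nan)
        with np.errstate(invalid="ignore"):
            flat = cand.ravel()
            if mode == "max":
                idx = np.nanargmax(flat)
            else:
                idx = np.nanargmin(flat)
        val = flat[idx]
        x, y = np.unravel_index(idx, cand.shape)
        key = val if mode == "max" else -val
        center = (int(x), int(y), int(z))
        # ties break to the first center in row-major (x, y, z) scan order
        if best is None or key > best[0] or (key == best[0] and center < best[1]):
            best = (key, center, float(val))
    if best is None:
        return None
    return best[1], best[2], n_kernel


def propagate_roi(roi: HotspotROI, target_map: ParametricMap) -> float:
    """Mean of the target map over the same disc voxels (grids must have
    identical dimensions; co-registration is assumed upstream)."""
    if roi.voxel_indices is None:
        off = disc_offsets(roi.radius_mm, target_map.voxel_size)
        xs = roi.center[0] + off[:, 0]
        ys = roi.center[1] + off[:, 1]
        zs = np.full(len(off), roi.center[2])
    else:
        xs, ys, zs = roi.voxel_indices
    shape = target_map.shape
    if np.any(xs < 0) or np.any(ys < 0) or np.any(xs >= shape[0]) or np.any(ys >= shape[1]) or np.any(zs >= shape[2]):
        raise ValueError("ROI does not fit inside the target map grid")
    return float(np.mean(target_map.values[xs, ys, zs]))
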