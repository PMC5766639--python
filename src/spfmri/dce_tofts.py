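"""Extended Tofts model fitting for DCE concentration curves.

Operates purely in concentration space: signal-to-concentration
conversion (T1 mapping, relaxivity) is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from spfmri.dwi_fitting import ParametricMap
from spfmri.signal_models import AIF, ToftsParams, tofts_concentration

__all__ = ["ConcentrationCurve", "ToftsFitResult", "fit_tofts", "fit_dce_volume"]

log = logging.getLogger(__name__)

# Bounded search region for the fit.
TOFTS_BOUNDS = {"Ktrans": (0.0, 2.0), "v_e": (1e-6, 1.0), "v_p": (0.0, 0.3)}

# Multi-start initializations (Ktrans, v_e, v_p); the residual surface is
# mildly multimodal so three spread starts are used and the best kept.
DEFAULT_STARTS = (
    (0.05, 0.2, 0.02),
    (0.3, 0.5, 0.05),
    (0.01, 0.05, 0.1),
)


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tissue concentration samples: times (min), Ct (mM)."""

    times: np.ndarray
    Ct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.Ct, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and Ct must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ValueError("times and Ct must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "Ct", c)


@dataclass(frozen=True)
class ToftsFitResult:
    params: ToftsParams
    residual_norm: float
    converged: bool
    flagged: bool = False


def fit_tofts(
    curve: ConcentrationCurve,
    aif: AIF,
    starts=DEFAULT_STARTS,
    dt: float = 0.005,
) -> ToftsFitResult:
    """Bounded multi-start nonlinear least squares against the extended
    Tofts forward model; returns the best-residual solution.

    An all-zero curve short-circuits to zero parameters with a flag.
    """
    if len(curve.times) < 10:
        raise ValueError("need at least 10 time points")
    lo, hi = aif.span
    if curve.times[-1] < lo or curve.times[0] > hi:
        raise ValueError("curve and AIF time spans do not overlap")
    t = np.clip(curve.times, lo, hi)

    if np.allclose(curve.Ct, 0.0):
        return ToftsFitResult(
            params=ToftsParams(0.0, 0.0, 0.0),
            residual_norm=0.0,
            converged=True,
            flagged=True,
        )

    lb = [TOFTS_BOUNDS["Ktrans"][0], TOFTS_BOUNDS["v_e"][0], TOFTS_BOUNDS["v_p"][0]]
    ub = [TOFTS_BOUNDS["Ktrans"][1], TOFTS_BOUNDS["v_e"][1], TOFTS_BOUNDS["v_p"][1]]

    # data-driven plasma-heavy start: keeps plasma-only curves out of the
    # degenerate ridge where Ktrans with tiny v_e mimics the v_p term
    cp = aif(t)
    denom = float(np.dot(cp, cp))
    vp0 = float(np.clip(np.dot(cp, curve.Ct) / denom, 0.0, 0.29)) if denom > 0 else 0.02
    starts = tuple(starts) + ((1e-3, 0.2, vp0),)

    def residuals(x):
        p = ToftsParams(Ktrans=x[0], v_e=min(x[1], 1.0 - x[2]), v_p=x[2])
        return tofts_concentration(p, aif, t, dt=dt) - curve.Ct

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, np.clip(x0, lb, ub), bounds=(lb, ub), xtol=1e-14, ftol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
    ktrans, ve, vp = (float(v) for v in best.x)
    params = ToftsParams(Ktrans=ktrans, v_e=min(ve, 1.0 - vp), v_p=vp)
    return ToftsFitResult(
        params=params,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def fit_dce_volume(
    volume: np.ndarray,
    times: np.ndarray,
    aif: AIF,
    mask: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    dt: float = 0.005,
) -> dict[str, ParametricMap]:
    """Voxelwise extended Tofts fit over a 4D (x, y, z, t) concentration
    volume; returns Ktrans, ve and vp maps."""
    volume = np.asarray(volume, dtype=float)
    times = np.asarray(times, dtype=float)
    if volume.ndim != 4 or volume.shape[3] != times.size:
        raise ValueError(
            f"volume 4th dimension does not match times length {times.size}"
        )
    spatial = volume.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} does not match volume {spatial}")
    if not mask.any():
        log.warning("empty mask: returning empty maps")

    meta = {"method": "tofts", "n_timepoints": int(times.size)}
    out = {
        name: ParametricMap(
            values=np.full(spatial, np.nan),
            mask=np.zeros(spatial, dtype=bool),
            voxel_size=voxel_size,
            parameter_name=name,
            meta=dict(meta),
        )
        for name in ("Ktrans", "ve", "vp")
    }
    for idx in np.argwhere(mask):
        curve = ConcentrationCurve(times, volume[tuple(idx)])
        fit = fit_tofts(curve, aif, dt=dt)
        if not fit.converged:
            continue
        x, y, z = idx
        for name, val in zip(
            ("Ktrans", "ve", "vp"),
            (fit.params.Ktrans, fit.params.v_e, fit.params.v_p),
        ):
            out[name].values[x, y, z] = val
            out[name].mask[x, y, z] = True
    return out
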