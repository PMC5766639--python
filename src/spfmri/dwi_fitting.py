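"""Estimation of SPF components, conventional ADC, and IVIM parameters
from multi-b-value DWI signals, per voxel and over whole volumes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from spfmri.signal_models import BValueScheme, IVIMParams, ivim_signal

__all__ = [
    "DWISeries",
    "SPFComponents",
    "ParametricMap",
    "IVIMFitResult",
    "two_point_adc",
    "compute_spf",
    "conventional_adc",
    "fit_ivim",
    "fit_volume",
    "IVIM_BOUNDS",
]

# Fitting bounds: 0 <= f <= 0.7, 1e-5 <= D <= 4e-3, D < D* <= 0.5 mm^2/s.
IVIM_BOUNDS = {"f": (0.0, 0.7), "D": (1e-5, 4e-3), "D_star": (1e-5, 0.5)}


@dataclass(frozen=True)
class DWISeries:
    """One signal value per b-value of a scheme, arbitrary units."""

    scheme: BValueScheme
    signals: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.signals, dtype=float)
        if s.ndim != 1 or s.size != len(self.scheme):
            raise ValueError(
                f"signals length {s.size} does not match scheme length {len(self.scheme)}"
            )
        object.__setattr__(self, "signals", s)

    def signal_at(self, b: float) -> float:
        return float(self.signals[self.scheme.index_of(b)])


@dataclass(frozen=True)
class SPFComponents:
    """The four two-point-ADC-derived quantities (mm^2/s and fraction).

    The identities adc_perf = adc_0_200 - adc_200_1000 and
    spf = adc_perf / adc_0_200 hold exactly as stored.  ``negative_perf``
    flags noise-driven negative adc_perf, which is retained unclipped.
    """

    adc_0_200: float
    adc_200_1000: float
    adc_perf: float
    spf: float
    negative_perf: bool = False


@dataclass
class ParametricMap:
    """Scalar per voxel on a 3D grid with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    parameter_name: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be 3-D arrays of identical shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite wherever mask is true")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class IVIMFitResult:
    params: IVIMParams
    S0: float
    residual_norm: float
    converged: bool
    at_bounds: bool = False


def two_point_adc(S_low, S_high, b_low: float, b_high: float):
    """Monoexponential two-point ADC: ln(S_low/S_high) / (b_high - b_low).

    May be negative for noisy inputs (S_high > S_low); returned as-is.
    """
    if b_high <= b_low or b_low < 0:
        raise ValueError(f"need b_high > b_low >= 0, got ({b_low}, {b_high})")
    S_low = np.asarray(S_low, dtype=float)
    S_high = np.asarray(S_high, dtype=float)
    if np.any(S_low <= 0) or np.any(S_high <= 0):
        raise ValueError("signals must be positive")
    out = np.log(S_low / S_high) / (b_high - b_low)
    return out if out.ndim else float(out)


def _range_adc(b: np.ndarray, s: np.ndarray) -> float:
    """Log-linear OLS decay rate over a b-value range (non-default path)."""
    slope = np.polyfit(b, np.log(s), 1)[0]
    return float(-slope)


def compute_spf(
    series: DWISeries,
    b_cut: float = 200.0,
    b_max: float = 1000.0,
    endpoints_only: bool = True,
) -> SPFComponents:
    """SPF components from a DWI series.

    Default uses exactly the three named b-values (0, b_cut, b_max):
    adc_0_200 from the (0, b_cut) pair, adc_200_1000 from (b_cut, b_max),
    then adc_perf and spf by their defining identities.  With
    ``endpoints_only=False`` each ADC is instead a log-linear fit over
    all b-values in its range (explicitly non-default).

    Raises if a required b-value is missing; returns spf=nan with the
    voxel flagged when adc_0_200 <= 0.
    """
    b = series.scheme.as_array()
    s = series.signals
    if np.any(s <= 0):
        raise ValueError("signals must be positive for SPF computation")
    if endpoints_only:
        s0 = series.signal_at(0.0)
        s_cut = series.signal_at(b_cut)
        s_max = series.signal_at(b_max)
        adc_low = two_point_adc(s0, s_cut, 0.0, b_cut)
        adc_high = two_point_adc(s_cut, s_max, b_cut, b_max)
    else:
        lo = b <= b_cut
        hi = (b >= b_cut) & (b <= b_max)
        if lo.sum() < 2 or hi.sum() < 2:
            raise ValueError("need at least two b-values in each range")
        adc_low = _range_adc(b[lo], s[lo])
        adc_high = _range_adc(b[hi], s[hi])
    adc_perf = adc_low - adc_high
    if adc_low > 0:
        spf = adc_perf / adc_low
    else:
        spf = float("nan")
    return SPFComponents(
        adc_0_200=adc_low,
        adc_200_1000=adc_high,
        adc_perf=adc_perf,
        spf=spf,
        negative_perf=bool(adc_perf < 0),
    )


def conventional_adc(series: DWISeries, b_max: float = 1000.0) -> float:
    """Clinical-routine ADC from the (0, b_max) signal pair."""
    return two_point_adc(
        series.signal_at(0.0), series.signal_at(b_max), 0.0, b_max
    )


def _segmented_ivim(b, s, b_cut):
    """Segmented estimate: D and intercept from log-signal at b >= b_cut,
    f from the intercept ratio, D* by bounded 1-D least squares."""
    hi = b >= b_cut
    slope, log_a = np.polyfit(b[hi], np.log(s[hi]), 1)
    d_lo, d_hi = IVIM_BOUNDS["D"]
    D = float(np.clip(-slope, d_lo, d_hi))
    at_bounds = not (d_lo < -slope < d_hi)
    intercept = float(np.exp(log_a))
    s0_obs = float(s[np.argmin(b)])
    f_lo, f_hi = IVIM_BOUNDS["f"]
    f_raw = 1.0 - intercept / s0_obs
    f = float(np.clip(f_raw, f_lo, f_hi))
    at_bounds = at_bounds or f_raw > f_hi

    ds_hi = IVIM_BOUNDS["D_star"][1]
    ds_lo = D * (1.0 + 1e-9)

    def sse(d_star):
        model = s0_obs * (f * np.exp(-b * d_star) + (1 - f) * np.exp(-b * D))
        return float(np.sum((s - model) ** 2))

    res = minimize_scalar(sse, bounds=(ds_lo, ds_hi), method="bounded")
    d_star = float(max(res.x, ds_lo))
    return f, D, d_star, s0_obs, at_bounds


def fit_ivim(
    series: DWISeries, b_cut: float = 200.0, refine: bool = True
) -> IVIMFitResult:
    """Fit the IVIM biexponential model to a DWI series.

    Strategy: segmented initialization (log-linear D from the high-b
    segment, f from the intercept, bounded 1-D search for D*) followed,
    by default, by full bounded nonlinear least squares over
    (f, D, D*, S0) started at the segmented solution.  ``refine=False``
    returns the pure segmented estimate, which carries a documented
    approximation bias when D* * b_cut is small.
    """
    b = series.scheme.as_array()
    s = series.signals
    if np.sum(b >= b_cut) < 3 or np.sum(b < b_cut) < 3:
        raise ValueError("need at least 3 b-values on each side of b_cut")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")

    f, D, d_star, s0, at_bounds = _segmented_ivim(b, s, b_cut)
    converged = True

    if refine:
        def residuals(x):
            fv, dv, dsv, s0v = x
            return s0v * (fv * np.exp(-b * dsv) + (1 - fv) * np.exp(-b * dv)) - s

        lb = [IVIM_BOUNDS["f"][0], IVIM_BOUNDS["D"][0], IVIM_BOUNDS["D_star"][0], 1e-12]
        ub = [IVIM_BOUNDS["f"][1], IVIM_BOUNDS["D"][1], IVIM_BOUNDS["D_star"][1], np.inf]
        x0 = np.clip([f, D, d_star, s0], lb, ub)
        sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        seg_cost = float(np.sum(residuals(x0) ** 2))
        if sol.success and 2 * sol.cost <= seg_cost + 1e-30:
            f, D, d_star, s0 = (float(v) for v in sol.x)
        converged = bool(sol.success)

    d_star = max(d_star, D * (1.0 + 1e-9))
    params = IVIMParams(f=min(f, 1.0 - 1e-12), D=D, D_star=d_star)
    resid = np.linalg.norm(ivim_signal(params, b, s0) - s)
    return IVIMFitResult(
        params=params,
        S0=float(s0),
        residual_norm=float(resid),
        converged=converged,
        at_bounds=at_bounds,
    )


_SPF_MAP_NAMES = ("SPF", "ADC_0_200", "ADC_200_1000", "ADC_perf")
_IVIM_MAP_NAMES = ("f", "D", "D_star")


def fit_volume(
    volume: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray | None = None,
    method: str = "spf",
    b_cut: float = 200.0,
    b_max: float = 1000.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    refine: bool = True,
) -> dict[str, ParametricMap]:
    """Voxelwise fitting over a 4D (x, y, z, b) volume.

    method: 'spf' -> SPF, ADC_0_200, ADC_200_1000, ADC_perf maps;
    'ivim' -> f, D, D_star maps; 'adc' -> ADC_0_1000 map.  Voxels with
    any non-positive signal (or failed fits) are masked, not floored.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[3] != len(scheme):
        raise ValueError(
            f"volume 4th dimension {volume.shape[-1] if volume.ndim == 4 else '?'} "
            f"does not match scheme length {len(scheme)}"
        )
    spatial = volume.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} does not match volume {spatial}")

    valid = mask & np.all(volume > 0, axis=-1) & np.all(np.isfinite(volume), axis=-1)
    meta = {"method": method, "b_cut": b_cut, "b_max": b_max,
            "scheme": list(scheme.b_values)}

    def new_map(name):
        return ParametricMap(
            values=np.full(spatial, np.nan),
            mask=np.zeros(spatial, dtype=bool),
            voxel_size=voxel_size,
            parameter_name=name,
            meta=dict(meta),
        )

    if method == "adc":
        out = {"ADC_0_1000": new_map("ADC_0_1000")}
        i0 = scheme.index_of(0.0)
        i1 = scheme.index_of(b_max)
        vals = np.full(spatial, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[valid] = np.log(volume[valid, i0] / volume[valid, i1]) / b_max
        out["ADC_0_1000"].values = vals
        out["ADC_0_1000"].mask = valid & np.isfinite(vals)
        return out

    if method == "spf":
        i0 = scheme.index_of(0.0)
        ic = scheme.index_of(b_cut)
        im = scheme.index_of(b_max)
        adc_lo = np.full(spatial, np.nan)
        adc_hi = np.full(spatial, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            adc_lo[valid] = np.log(volume[valid, i0] / volume[valid, ic]) / b_cut
            adc_hi[valid] = np.log(volume[valid, ic] / volume[valid, im]) / (b_max - b_cut)
        perf = adc_lo - adc_hi
        with np.errstate(invalid="ignore", divide="ignore"):
            spf = np.where(adc_lo > 0, perf / adc_lo, np.nan)
        out = {}
        for name, arr in zip(
            _SPF_MAP_NAMES, (spf, adc_lo, adc_hi, perf)
        ):
            m = new_map(name)
            m.values = arr
            m.mask = valid & np.isfinite(arr)
            out[name] = m
        return out

    if method == "ivim":
        out = {name: new_map(name) for name in _IVIM_MAP_NAMES}
        for idx in np.argwhere(valid):
            series = DWISeries(scheme, volume[tuple(idx)])
            try:
                fit = fit_ivim(series, b_cut=b_cut, refine=refine)
            except ValueError:
                continue
            if not fit.converged:
                continue
            x, y, z = idx
            for name, val in zip(
                _IVIM_MAP_NAMES, (fit.params.f, fit.params.D, fit.params.D_star)
            ):
                out[name].values[x, y, z] = val
                out[name].mask[x, y, z] = True
        return out

    raise ValueError(f"unknown method {method!r}; expected spf, ivim or adc")
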