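"""Bounded voxelwise fitting of the four diffusion models.

The measured per-direction signal is first orientation-averaged (geometric
mean across directions per b-shell — the arithmetic mean of log-signals),
then each model is fitted to the normalized decay S(b)/S(0) by bounded
nonlinear least squares over all b-values.  S(0) is fixed to the measured
b=0 intensity, not fitted.

Model-specific strategies:

* mono: log-linear initialization, single-parameter bounded refinement;
* IVIM: segmented fit — log-linear estimate of the slow coefficient D on
  b >= split (default 200 s/mm², above which perfusion has decayed), then
  (f, D*) with D fixed, then one joint bounded refinement parameterized as
  (D, D* - D, f) so D < D* holds by construction;
* stretched exponential: initialized from the mono fit (DDC <- ADC,
  alpha <- 0.9);
* CTRW: multi-start over (alpha, beta) initial pairs to avoid the local
  minima of the exchangeable heterogeneity indices; ties broken toward
  larger alpha.

All fits are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .models import (DIFFUSIVITY_SCALE, CTRWParams, IVIMParams, MonoParams,
                     SEMParams, ctrw_signal, ivim_signal, mono_signal,
                     sem_signal)
from .scheme import BValueScheme, DWISignal

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "ParameterMap", "DirectionAverage",
           "average_directions", "fit_mono", "fit_ivim_segmented", "fit_sem",
           "fit_ctrw", "fit_parameter_maps", "MODEL_PARAMETERS",
           "PARAMETER_NAMES"]

#: canonical parameter names per model, matching the 9 reported map types
MODEL_PARAMETERS = {
    "mono": ("Mono_ADC",),
    "ivim": ("IVIM_D", "IVIM_Dstar", "IVIM_f"),
    "sem": ("SEM_DDC", "SEM_alpha"),
    "ctrw": ("CTRW_Dm", "CTRW_alpha", "CTRW_beta"),
}
PARAMETER_NAMES = tuple(n for names in MODEL_PARAMETERS.values() for n in names)


@dataclass(frozen=True)
class FitConfig:
    """Bounds and solver settings shared by all model fits.

    Diffusivity bounds are in 1e-3 mm²/s.  ``ivim_split_b`` must be one of
    the scheme's b-values.  The loss is the sum of squared residuals on the
    normalized signal.
    """

    adc_bounds: tuple[float, float] = (1e-4, 4.0)
    ddc_bounds: tuple[float, float] = (1e-4, 4.0)
    dm_bounds: tuple[float, float] = (1e-4, 4.0)
    d_bounds: tuple[float, float] = (1e-4, 3.0)
    d_star_max: float = 500.0
    f_bounds: tuple[float, float] = (0.0, 0.5)
    alpha_bounds: tuple[float, float] = (0.1, 1.0)
    beta_bounds: tuple[float, float] = (0.1, 1.0)
    ivim_split_b: float = 200.0
    max_iterations: int = 200
    tol: float = 1e-10
    ctrw_starts: tuple[tuple[float, float], ...] = (
        (0.9, 0.95), (0.7, 0.9), (0.95, 0.8))

    def __post_init__(self) -> None:
        for name in ("adc_bounds", "ddc_bounds", "dm_bounds", "d_bounds",
                     "f_bounds", "alpha_bounds", "beta_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper")

    def check_scheme(self, scheme: BValueScheme) -> None:
        if self.ivim_split_b not in scheme.b_values:
            raise ValueError(
                f"ivim_split_b={self.ivim_split_b} is not in the b-value scheme")


@dataclass
class FitResult:
    """Fitted parameters with residual sum of squares and status flags."""

    params: object
    rss: float
    success: bool = True
    flags: tuple[str, ...] = ()

    @property
    def values(self) -> dict[str, float]:
        p = self.params
        if isinstance(p, MonoParams):
            return {"Mono_ADC": p.adc}
        if isinstance(p, IVIMParams):
            return {"IVIM_D": p.d, "IVIM_Dstar": p.d_star, "IVIM_f": p.f}
        if isinstance(p, SEMParams):
            return {"SEM_DDC": p.ddc, "SEM_alpha": p.alpha}
        if isinstance(p, CTRWParams):
            return {"CTRW_Dm": p.dm, "CTRW_alpha": p.alpha, "CTRW_beta": p.beta}
        raise TypeError(f"unknown parameter type {type(p)}")


@dataclass
class DirectionAverage:
    """Orientation-averaged 4D volume plus per-(voxel, b) validity."""

    data: np.ndarray
    valid: np.ndarray
    n_excluded: int = 0


@dataclass
class ParameterMap:
    """One fitted parametric map aligned to the input voxel grid."""

    model: str
    name: str
    data: np.ndarray
    rss: np.ndarray
    valid: np.ndarray


def average_directions(signal_5d: np.ndarray,
                       scheme: BValueScheme) -> DirectionAverage:
    """Geometric mean across diffusion directions, per b-shell.

    ``signal_5d`` has shape (..., n_b, n_directions).  Non-zero shells are
    averaged as the arithmetic mean of log-signals (geometric mean); the b=0
    shell is passed through as a plain mean (no diffusion encoding to
    average over).  Non-positive intensities are excluded from the log-mean
    with a logged count; voxels/shells with no valid direction are flagged.
    """
    sig = np.asarray(signal_5d, dtype=float)
    if sig.ndim < 2:
        raise ValueError("expected (..., n_b, n_directions) array")
    if sig.shape[-2] != scheme.n_b:
        raise ValueError("b axis length does not match the scheme")
    if sig.shape[-1] != scheme.n_directions:
        raise ValueError("direction axis length does not match the scheme")
    ok = sig > 0
    n_excluded = int(sig.size - ok.sum())
    if n_excluded:
        logger.warning("direction averaging: excluded %d non-positive samples",
                       n_excluded)
    n_ok = ok.sum(axis=-1)
    valid = n_ok > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logmean = np.where(ok, np.log(np.where(ok, sig, 1.0)), 0.0).sum(axis=-1)
        logmean = np.where(valid, logmean / np.maximum(n_ok, 1), 0.0)
        geo = np.exp(logmean)
        arith = np.where(ok, sig, 0.0).sum(axis=-1) / np.maximum(n_ok, 1)
    data = geo.copy()
    data[..., 0] = arith[..., 0]        # b=0 passed through
    data[~valid] = np.nan
    return DirectionAverage(data=data, valid=valid, n_excluded=n_excluded)


def _lsq(fun, x0, bounds, cfg: FitConfig):
    return least_squares(fun, x0=np.asarray(x0, float),
                         bounds=bounds, method="trf",
                         max_nfev=cfg.max_iterations * (len(x0) + 1) * 4,
                         xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol)


def _rss(y, yhat) -> float:
    return float(np.sum((y - yhat) ** 2))


def _normalized(sig: DWISignal) -> tuple[np.ndarray, np.ndarray]:
    b = sig.scheme.b
    y = sig.normalized
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("signals must be finite and positive")
    return b, y


def _loglinear_slope(b: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of ln(y) vs b; returns (diffusivity, intercept)."""
    res = linregress(b, np.log(y))
    return -res.slope / DIFFUSIVITY_SCALE, res.intercept


def fit_mono(sig: DWISignal, cfg: FitConfig = FitConfig()) -> FitResult:
    """Fit exp(-b*ADC) over all b-values by bounded least squares."""
    b, y = _normalized(sig)
    lo, hi = cfg.adc_bounds
    if np.ptp(y) < 1e-12:
        return FitResult(MonoParams(lo), _rss(y, np.exp(-b * lo * 1e-3)),
                         success=False, flags=("degenerate",))
    adc0 = float(np.clip(_loglinear_slope(b, y)[0], lo, hi))
    res = _lsq(lambda p: np.exp(-b * p[0] * DIFFUSIVITY_SCALE) - y,
               [adc0], ([lo], [hi]), cfg)
    params = MonoParams(float(np.clip(res.x[0], lo, hi)))
    return FitResult(params, _rss(y, mono_signal(b, params)))


def fit_ivim_segmented(sig: DWISignal,
                       cfg: FitConfig = FitConfig()) -> FitResult:
    """Segmented IVIM fit: D from high-b, then (f, D*), then joint refinement."""
    cfg.check_scheme(sig.scheme)
    b, y = _normalized(sig)
    hi_mask = b >= cfg.ivim_split_b
    if hi_mask.sum() < 2 or (~hi_mask).sum() < 1:
        raise ValueError("scheme must bracket ivim_split_b")
    dlo, dhi = cfg.d_bounds
    flo, fhi = cfg.f_bounds

    # stage 1: slow diffusion from the perfusion-free high-b segment
    d1, intercept = _loglinear_slope(b[hi_mask], y[hi_mask])
    d1 = float(np.clip(d1, dlo, dhi))
    f0 = float(np.clip(1.0 - np.exp(intercept), flo + 1e-6, fhi))
    fallback = FitResult(IVIMParams(d1, max(10.0 * d1, d1 + 1.0), 0.0),
                         np.inf, success=False, flags=("stage2-failed",))

    def two_comp(d, d_star, f):
        bd = b * DIFFUSIVITY_SCALE
        return f * np.exp(-bd * d_star) + (1.0 - f) * np.exp(-bd * d)

    try:
        # stage 2: perfusion compartment with D frozen
        res2 = _lsq(lambda p: two_comp(d1, p[0], p[1]) - y,
                    [max(10.0, 2.0 * d1), f0],
                    ([d1 + 1e-6, flo], [cfg.d_star_max, fhi]), cfg)
        dstar2, f2 = res2.x
        # stage 3: joint refinement, delta = D* - D keeps the ordering
        res3 = _lsq(lambda p: two_comp(p[0], p[0] + p[1], p[2]) - y,
                    [d1, max(dstar2 - d1, 1e-3), f2],
                    ([dlo, 1e-3, flo], [dhi, cfg.d_star_max, fhi]), cfg)
        d, delta, f = res3.x
        params = IVIMParams(float(d), float(d + delta), float(f))
    except Exception:       # pragma: no cover - solver breakdown safeguard
        logger.warning("IVIM segmented fit failed; returning stage-1 estimate")
        fallback.rss = _rss(y, ivim_signal(b, fallback.params))
        return fallback
    return FitResult(params, _rss(y, ivim_signal(b, params)))


def fit_sem(sig: DWISignal, cfg: FitConfig = FitConfig()) -> FitResult:
    """Fit the stretched exponential, initialized from the mono fit."""
    b, y = _normalized(sig)
    mono = fit_mono(sig, cfg)
    dlo, dhi = cfg.ddc_bounds
    alo, ahi = cfg.alpha_bounds
    x0 = [float(np.clip(mono.params.adc, dlo, dhi)), 0.9]

    def resid(p):
        return np.exp(-((b * p[0] * DIFFUSIVITY_SCALE) ** p[1])) - y

    res = _lsq(resid, x0, ([dlo, alo], [dhi, ahi]), cfg)
    params = SEMParams(float(res.x[0]), float(res.x[1]))
    flags = ("degenerate",) if "degenerate" in mono.flags else ()
    return FitResult(params, _rss(y, sem_signal(b, params)), flags=flags)


def fit_ctrw(sig: DWISignal, cfg: FitConfig = FitConfig()) -> FitResult:
    """Multi-start bounded fit of the CTRW model; ties favor larger alpha."""
    b, y = _normalized(sig)
    mono = fit_mono(sig, cfg)
    dlo, dhi = cfg.dm_bounds
    alo, ahi = cfg.alpha_bounds
    blo, bhi = cfg.beta_bounds
    dm0 = float(np.clip(mono.params.adc, dlo, dhi))

    def resid(p):
        params = CTRWParams(max(p[0], dlo), p[1], p[2])
        return ctrw_signal(b, params) - y

    candidates: list[tuple[float, float, CTRWParams]] = []
    for a0, b0 in cfg.ctrw_starts:
        try:
            res = _lsq(resid, [dm0, a0, b0],
                       ([dlo, alo, blo], [dhi, ahi, bhi]), cfg)
        except Exception:   # pragma: no cover - single-start breakdown
            continue
        params = CTRWParams(float(res.x[0]), float(res.x[1]), float(res.x[2]))
        candidates.append((_rss(y, ctrw_signal(b, params)), params.alpha, params))
    if not candidates:
        raise RuntimeError("all CTRW starts failed")
    best_rss = min(c[0] for c in candidates)
    # within-tolerance ties broken toward larger alpha
    tied = [c for c in candidates if c[0] <= best_rss + 1e-10]
    _, _, params = max(tied, key=lambda c: c[1])
    return FitResult(params, best_rss)


_FITTERS = {"mono": fit_mono, "ivim": fit_ivim_segmented,
            "sem": fit_sem, "ctrw": fit_ctrw}


def fit_parameter_maps(volume_4d: np.ndarray, scheme: BValueScheme,
                       mask: np.ndarray, model: str,
                       cfg: FitConfig = FitConfig()) -> list[ParameterMap]:
    """Fit one model voxelwise inside a mask; one map per model parameter.

    Voxel-level failures (non-positive signals, solver errors) are recorded
    in the validity mask and never abort the volume.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    vol = np.asarray(volume_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vol.ndim != 4 or vol.shape[-1] != scheme.n_b:
        raise ValueError("expected (X, Y, Z, n_b) volume matching the scheme")
    if mask.shape != vol.shape[:3]:
        raise ValueError("mask must align with the volume grid")
    names = MODEL_PARAMETERS[model]
    shape = vol.shape[:3]
    data = {n: np.full(shape, np.nan) for n in names}
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("fit_parameter_maps: empty mask, returning empty maps")
    n_failed = 0
    fitter = _FITTERS[model]
    for i, j, k in idx:
        curve = vol[i, j, k]
        try:
            s0 = curve[0]
            if not np.isfinite(s0) or s0 <= 0:
                raise ValueError("non-positive b=0 signal")
            sig = DWISignal(scheme, float(s0), curve)
            fit = fitter(sig, cfg)
        except Exception:
            n_failed += 1
            continue
        for n, v in fit.values.items():
            data[n][i, j, k] = v
        rss[i, j, k] = fit.rss
        valid[i, j, k] = True
    if n_failed:
        logger.warning("fit_parameter_maps(%s): %d/%d voxels failed",
                       model, n_failed, len(idx))
    return [ParameterMap(model, n, data[n], rss, valid) for n in names]
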