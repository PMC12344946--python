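"""Forward signal equations of the four multi-b-value diffusion models.

All models express the normalized decay S(b)/S(0) of the direction-averaged
diffusion-weighted signal as a function of the b-value (s/mm²):

* mono-exponential:          exp(-b * ADC)
* IVIM (bi-exponential):     f * exp(-b * D*) + (1 - f) * exp(-b * D)
* stretched exponential:     exp(-(b * DDC)^alpha)
* continuous-time random walk: E_alpha(-(b * D_m)^beta)

Diffusivities (ADC, D, D*, DDC, D_m) are stored and reported in units of
1e-3 mm²/s — the scale on which clinical values are conventionally printed
(healthy white matter ADC ~0.7, glioma ~1.0-1.4) — and converted internally
before forming the dimensionless product b*D.  E_alpha is the one-parameter
Mittag-Leffler function (see :mod:`qdwi.special`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .special import mittag_leffler_neg

__all__ = ["MonoParams", "IVIMParams", "SEMParams", "CTRWParams",
           "mono_signal", "ivim_signal", "sem_signal", "ctrw_signal",
           "DIFFUSIVITY_SCALE"]

#: diffusivities are expressed in units of 1e-3 mm²/s
DIFFUSIVITY_SCALE = 1e-3


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or not np.all(np.isfinite(b)):
        raise ValueError("b-values must be finite and non-negative")
    return b


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential model: apparent diffusion coefficient (1e-3 mm²/s)."""

    adc: float

    def __post_init__(self) -> None:
        if not (0.0 < self.adc <= 4.0):
            raise ValueError("adc must lie in (0, 4] (units of 1e-3 mm²/s)")


@dataclass(frozen=True)
class IVIMParams:
    """IVIM model: slow/fast diffusivities (1e-3 mm²/s) and perfusion fraction."""

    d: float
    d_star: float
    f: float

    def __post_init__(self) -> None:
        if not (0.0 < self.d):
            raise ValueError("d must be positive")
        if not (self.d < self.d_star):
            raise ValueError("d_star must exceed d (pseudo-diffusion is fast)")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("perfusion fraction f must lie in [0, 1]")


@dataclass(frozen=True)
class SEMParams:
    """Stretched exponential: distributed diffusion coefficient and alpha."""

    ddc: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ddc):
            raise ValueError("ddc must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("heterogeneity index alpha must lie in (0, 1]")


@dataclass(frozen=True)
class CTRWParams:
    """CTRW model: anomalous diffusion coefficient D_m and the temporal (alpha)
    and spatial (beta) diffusion heterogeneity indices.

    Both indices are bounded above by 1: beta through the normalization of the
    waiting-time/jump-length formulation, alpha by subdiffusive physics.
    """

    dm: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.dm):
            raise ValueError("dm must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("temporal index alpha must lie in (0, 1]")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("spatial index beta must lie in (0, 1]")


def mono_signal(b, params: MonoParams):
    """S(b)/S(0) = exp(-b * ADC)."""
    b = _check_b(b)
    return np.exp(-b * params.adc * DIFFUSIVITY_SCALE)


def ivim_signal(b, params: IVIMParams):
    """S(b)/S(0) = f exp(-b D*) + (1 - f) exp(-b D)."""
    b = _check_b(b)
    bd = b * DIFFUSIVITY_SCALE
    return (params.f * np.exp(-bd * params.d_star)
            + (1.0 - params.f) * np.exp(-bd * params.d))


def sem_signal(b, params: SEMParams):
    """S(b)/S(0) = exp(-(b * DDC)^alpha)."""
    b = _check_b(b)
    return np.exp(-((b * params.ddc * DIFFUSIVITY_SCALE) ** params.alpha))


def ctrw_signal(b, params: CTRWParams):
    """S(b)/S(0) = E_alpha(-(b * D_m)^beta)."""
    b = _check_b(b)
    x = (b * params.dm * DIFFUSIVITY_SCALE) ** params.beta
    return mittag_leffler_neg(x, params.alpha)
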