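"""Median-effect dose-response fitting and the Chou-Talalay combination index.

The median-effect equation relates dose D to fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m

so log10(fa/(1-fa)) is linear in log10(D) with slope m (curve shape) and
median-effect dose Dm = 10^(-intercept/m), the dose giving fa = 0.5. For a
combination observed at fraction affected fa, the combination index is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where Dx_i(fa) = Dm_i (fa/(1-fa))^(1/m_i) is the single-agent dose of drug i
producing the same effect (mutually exclusive form; the non-exclusive variant
adds the cross term). CI < 1 indicates synergism, CI = 1 additivity, CI > 1
antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import NersigError

__all__ = [
    "DoseResponseCurve",
    "MedianEffectFit",
    "CIResult",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
]

FA_BOUNDS = (0.005, 0.995)  # linearization blows up outside this band


@dataclass
class DoseResponseCurve:
    """Single-drug dose vs fraction-affected points."""

    drug: str
    doses: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.doses.size != self.fa.size:
            raise NersigError("doses and fa differ in length")
        if self.doses.size < 2 or np.unique(self.doses).size < 2:
            raise NersigError("need >= 2 distinct doses")
        if np.any(self.doses <= 0):
            raise NersigError("doses must be > 0")


@dataclass
class MedianEffectFit:
    drug: str
    m: float  # slope (sigmoidicity)
    dm: float  # median-effect dose, same units as the input doses
    r: float  # correlation coefficient of the linearized fit


@dataclass
class CIResult:
    d1: float
    d2: float
    fa_observed: float
    ci: float
    call: str  # synergism | additive | antagonism


def _check_fa(fa: np.ndarray, clip: bool) -> np.ndarray:
    fa = np.asarray(fa, dtype=float)
    lo, hi = FA_BOUNDS
    if clip:
        return np.clip(fa, lo, hi)
    bad = np.flatnonzero((fa < lo) | (fa > hi))
    if bad.size:
        raise NersigError(
            f"fraction affected {fa.flat[bad[0]]:.4g} at point {bad[0]} outside "
            f"[{lo}, {hi}]; pass clip=True to clip"
        )
    return fa


def fit_median_effect(curve: DoseResponseCurve, clip: bool = False) -> MedianEffectFit:
    """Fit (m, Dm) by ordinary least squares on the median-effect linearization."""
    fa = _check_fa(curve.fa, clip)
    x = np.log10(curve.doses)
    y = np.log10(fa / (1.0 - fa))
    if x.size == 2:
        m = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - m * x[0]
        r = 1.0
    else:
        fit = stats.linregress(x, y)
        m, intercept, r = fit.slope, fit.intercept, fit.rvalue
    if m == 0:
        raise NersigError("degenerate fit: zero median-effect slope")
    dm = 10.0 ** (-intercept / m)
    return MedianEffectFit(drug=curve.drug, m=float(m), dm=float(dm), r=float(r))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose of the fitted drug producing fraction affected fa (Dx)."""
    if not 0.0 < fa < 1.0:
        raise NersigError("fa must lie strictly in (0, 1)")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def _call(ci: float, additive_band: tuple[float, float] | None) -> str:
    if additive_band is None:  # strict textbook rule: measure-zero additivity
        if ci < 1.0:
            return "synergism"
        if ci == 1.0:
            return "additive"
        return "antagonism"
    lo, hi = additive_band
    if ci < lo:
        return "synergism"
    if ci <= hi:
        return "additive"
    return "antagonism"


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa: float,
    exclusive: bool = True,
    additive_band: tuple[float, float] | None = (0.9, 1.1),
) -> CIResult:
    """Combination index of a (d1, d2) dose pair observed at effect fa.

    ``exclusive=True`` (default) uses the two-term mutually exclusive form;
    ``exclusive=False`` adds the non-exclusive cross term d1*d2/(Dx1*Dx2).
    ``additive_band=None`` applies the strict CI<1 / CI=1 / CI>1 rule instead
    of the default (0.9, 1.1) additivity band.
    """
    if d1 <= 0 or d2 <= 0:
        raise NersigError("combination doses must be > 0")
    if not 0.0 < fa < 1.0:
        raise NersigError("observed fa must lie strictly in (0, 1)")
    dx1 = dose_for_effect(fit1, fa)
    dx2 = dose_for_effect(fit2, fa)
    ci = d1 / dx1 + d2 / dx2
    if not exclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    return CIResult(d1=d1, d2=d2, fa_observed=fa, ci=float(ci), call=_call(ci, additive_band))
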