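"""Gibbs adsorption analysis of surface-tension titrations.

Below the CMC the surface tension γ of an ionic surfactant falls linearly in
log₁₀ C; above it the curve plateaus.  The pre-CMC slope dγ/dlogC gives the
maximum surface excess via the Gibbs adsorption isotherm,

    Γmax = −(dγ/dlogC) / (2.303 · n · R · T)        [mol m⁻², slope in N/m]

with n = 2 for a fully dissociated 1:1 ionic surfactant, and the minimum
area per adsorbed molecule is A_min = 1 / (N_A · Γmax).  Intermediates are
never rounded: A_min is always computed from the unrounded Γmax (rounding
Γmax to two significant figures before inverting shifts A_min by ~0.5 Å²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    AVOGADRO,
    R,
    DomainError,
    InsufficientDataError,
    ResponseKind,
    TitrationSeries,
    logger,
)
from .packing import PackingResult, TailGeometry, packing_parameter

#: 2.303 appears verbatim in the isotherm (log₁₀ convention), not ln 10
LOG10_FACTOR = 2.303

#: max pairwise γ spread (mN/m) within the terminal plateau run
PLATEAU_SPREAD = 0.5


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    indices: tuple[int, ...]
    rss: float


@dataclass(frozen=True)
class AdsorptionResult:
    """Gibbs-chain output for one surface-tension titration."""

    slope: float              # dγ/dlogC, mN m⁻¹ per decade
    gamma_max: float          # mol cm⁻²
    a_min: float              # Å²
    cmc_tension: float | None  # mM, descending ∩ plateau
    plateau_gamma: float | None  # mN/m
    n_prefactor: int
    temperature_k: float
    window: tuple[int, ...]   # indices of points in the descending fit
    flags: tuple[str, ...] = ()
    packing: PackingResult | None = None


def surface_excess(slope: float, temperature_k: float, n_prefactor: int = 2) -> float:
    """Maximum surface excess Γmax in mol cm⁻².

    ``slope`` is dγ/dlogC in mN/m per decade (negative for a
    surface-active solute); ``n_prefactor`` counts the species adsorbing
    per molecule (2 for a monovalent ionic surfactant and its counterion).
    """
    if temperature_k <= 0:
        raise DomainError("temperature must be positive (K)")
    if n_prefactor not in (1, 2, 3):
        raise DomainError(f"n_prefactor must be 1, 2 or 3, got {n_prefactor}")
    # mN/m → N/m, result in mol/m², then ×1e-4 → mol/cm²
    gamma_si = -slope * 1e-3 / (LOG10_FACTOR * n_prefactor * R * temperature_k)
    return gamma_si * 1e-4


def min_area(gamma_max: float) -> float:
    """Minimum area per molecule, Å², from Γmax in mol cm⁻² (1 cm² = 10¹⁶ Å²)."""
    if gamma_max <= 0:
        raise DomainError("gamma_max must be positive")
    return 1e16 / (AVOGADRO * gamma_max)


def _terminal_plateau(resp: np.ndarray, spread: float = PLATEAU_SPREAD) -> int:
    """Index where the terminal plateau begins: the longest suffix whose
    pairwise γ spread is ≤ ``spread``."""
    start = len(resp) - 1
    lo = hi = resp[-1]
    for i in range(len(resp) - 2, -1, -1):
        lo2, hi2 = min(lo, resp[i]), max(hi, resp[i])
        if hi2 - lo2 <= spread:
            lo, hi, start = lo2, hi2, i
        else:
            break
    return start


def pre_cmc_slope(
    series: TitrationSeries,
    window: tuple[float, float] | None = None,
    plateau_spread: float = PLATEAU_SPREAD,
) -> LineFit:
    """Least-squares slope of γ versus log₁₀(C/mM) over the descending branch.

    By default the window is every point before the terminal plateau (the
    longest final run with γ spread ≤ 0.5 mN/m); an explicit concentration
    window ``(c_lo, c_hi)`` overrides it.
    """
    if series.response_kind is not ResponseKind.SURFACE_TENSION:
        raise DomainError(f"expected a surface-tension series, got {series.response_kind.value}")
    conc, resp = series.concentration, series.response
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive for a log fit")

    if window is not None:
        idx = np.flatnonzero((conc >= window[0]) & (conc <= window[1]))
    else:
        idx = np.arange(_terminal_plateau(resp, plateau_spread))
        if len(idx) == 0:
            # whole curve is a plateau: flat, non-surface-active
            return LineFit(slope=0.0, intercept=float(np.mean(resp)), indices=(), rss=0.0)
    if len(idx) < 3:
        raise InsufficientDataError("need ≥ 3 points in the descending window")

    x = np.log10(conc[idx])
    y = resp[idx]
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    return LineFit(slope=float(slope), intercept=float(intercept),
                   indices=tuple(int(i) for i in idx), rss=rss)


def analyze_tension(
    series: TitrationSeries,
    n_prefactor: int = 2,
    window: tuple[float, float] | None = None,
    tail: TailGeometry | None = None,
    plateau_spread: float = PLATEAU_SPREAD,
) -> AdsorptionResult:
    """Full Gibbs chain: slope → Γmax → A_min (→ CPP when a tail is given).

    The tension-derived CMC is the abscissa where the descending fitted line
    meets the horizontal fit to the terminal plateau.
    """
    series.require_points(4)
    fit = pre_cmc_slope(series, window=window, plateau_spread=plateau_spread)
    flags: list[str] = []
    if fit.slope >= 0:
        flags.append("non-surface-active")

    plateau_start = _terminal_plateau(series.response, plateau_spread)
    plateau_idx = np.arange(plateau_start, len(series.response))
    interior_plateau = len(plateau_idx) >= 2 and plateau_start > 0
    plateau_gamma = float(np.mean(series.response[plateau_idx])) if interior_plateau else None

    cmc_tension = None
    if plateau_gamma is not None and fit.slope < 0:
        log_cmc = (plateau_gamma - fit.intercept) / fit.slope
        cmc_tension = float(10.0 ** log_cmc)

    gamma_max = None
    a_min = None
    packing = None
    if fit.slope < 0:
        gamma_max = surface_excess(fit.slope, series.temperature_k, n_prefactor)
        a_min = min_area(gamma_max)
        if tail is not None:
            packing = packing_parameter(tail.volume, a_min, tail.length)
    elif fit.slope == 0:
        gamma_max = 0.0

    logger.info(
        "tension fit: slope=%.4g mN/m/decade gamma_max=%s a_min=%s cmc=%s (window=%s)",
        fit.slope, gamma_max, a_min, cmc_tension, fit.indices,
    )
    return AdsorptionResult(
        slope=fit.slope,
        gamma_max=gamma_max if gamma_max is not None else float("nan"),
        a_min=a_min if a_min is not None else float("nan"),
        cmc_tension=cmc_tension,
        plateau_gamma=plateau_gamma,
        n_prefactor=n_prefactor,
        temperature_k=series.temperature_k,
        window=fit.indices,
        flags=tuple(flags),
        packing=packing,
    )
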