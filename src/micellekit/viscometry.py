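"""Relative-viscosity virial analysis, shape factors, and micelle hydration.

For a dilute micellar solution the relative viscosity expands in the
hydrodynamic volume fraction φ of the micelles,

    ηr = 1 + ν φ + k₁ (ν φ)² + O(φ³),     φ = Vshyd · N_A · (c_s − c₁)

with c in mol/L, Vshyd the hydrated volume per surfactant molecule (nm³,
so Vshyd·N_A·10⁻²⁴ is per mol/L), c₁ the free-monomer concentration (taken
as the CMC), ν an Einstein-type shape factor (2.5 for spheres, larger for
rods), and k₁ a pairwise hydrodynamic-interaction coefficient.  Fitting
ηr − 1 = p₁ x + p₂ x² through the origin gives Vshyd = p₁/(ν N_A 10⁻²⁴)
and k₁ = p₂/p₁².

For a cylindrical micelle of axial ratio L/d, the equivalent prolate
ellipsoid of equal length and volume has axial ratio
J = (L/d)·[2/(3 − d/L)]^½ (so J = 1 exactly for a sphere), and

    ν = 2.5 + 0.407 (J − 1)^1.508                  for 1 < J < 15
    ν = 1.6 + (J²/15)·[1/(ln 2J − 1.5) + 3/(ln 2J − 0.5)]   for J > 15

Subtracting the anhydrous molecular volume from Vshyd gives the solvation
shell volume, converted to water (0.030 nm³) and cosolvent (urea,
0.075 nm³) molecule counts.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .io import (
    AVOGADRO,
    DomainError,
    InsufficientDataError,
    ResponseKind,
    SolventSpec,
    SurfactantSpec,
    TitrationSeries,
    logger,
)

#: nm³ per molecule → L per mol/L unit bookkeeping: Vshyd[nm³]·N_A·1e-24 is
#: the volume fraction per (mol/L) of micellized surfactant
NM3_PER_MOLECULE_TO_PER_MOLAR = AVOGADRO * 1e-24

#: shape factor of a sphere
NU_SPHERE = 2.5

#: equivalent-prolate axial ratio where the short-rod and long-rod formulas meet
J_CROSSOVER = 15.0


class MicelleRegime(str, enum.Enum):
    SPHERE = "sphere"
    SHORT_ROD = "short_rod"   # 1 < J < 15
    LONG_ROD = "long_rod"     # J > 15


@dataclass(frozen=True)
class ShapeModel:
    axial_ratio: float  # L/d of the cylinder
    j: float            # equivalent prolate axial ratio
    nu: float           # shape factor
    regime: MicelleRegime


@dataclass(frozen=True)
class ViscosityFit:
    p1: float       # per (mol/L) of micellized surfactant
    p2: float       # per (mol/L)²
    k1: float       # p2 / p1²
    nu: float
    v_shyd: float   # nm³
    c1_mM: float    # free monomer concentration used (≈ CMC)
    rss: float
    n_points: int
    flags: tuple[str, ...] = ()


class HydrationScenario(str, enum.Enum):
    DIRECT = "direct"
    CASE_I_CYLINDRICAL = "case_I_cylindrical"
    CASE_II_SPHERICAL = "case_II_spherical"


@dataclass(frozen=True)
class HydrationBudget:
    """Volume bookkeeping of one hydrated surfactant molecule (all nm³)."""

    v_shyd: float
    v_molecule: float
    v_water_total: float
    n_water: int                 # nearest integer
    v_cosolvent_total: float
    n_cosolvent: float           # one-decimal convention
    scenario: HydrationScenario = HydrationScenario.DIRECT
    flags: tuple[str, ...] = ()


def relative_viscosity(
    efflux_sample: float,
    efflux_solvent: float,
    calib_sample: float = 1.0,
    calib_solvent: float = 1.0,
) -> float:
    """ηr from capillary efflux times: (t·k)_sample / (t·k)_solvent.

    The calibration constants convert efflux time to kinematic viscosity;
    with a single viscometer they cancel and ηr is the time ratio.
    """
    vals = (efflux_sample, efflux_solvent, calib_sample, calib_solvent)
    if any(v <= 0 for v in vals):
        raise DomainError("efflux times and calibration constants must be positive")
    return (efflux_sample * calib_sample) / (efflux_solvent * calib_solvent)


def efflux_to_relative_viscosity(
    series: TitrationSeries, efflux_solvent: float, calib_sample: float = 1.0,
    calib_solvent: float = 1.0,
) -> TitrationSeries:
    """Convert an efflux-time titration to relative viscosities."""
    if series.response_kind is not ResponseKind.EFFLUX_TIME:
        raise DomainError(f"expected efflux times, got {series.response_kind.value}")
    eta_r = np.array([
        relative_viscosity(t, efflux_solvent, calib_sample, calib_solvent)
        for t in series.response
    ])
    return TitrationSeries(
        concentration=series.concentration, response=eta_r,
        response_kind=ResponseKind.RELATIVE_VISCOSITY,
        temperature_c=series.temperature_c,
    )


def micellar_volume_fraction(c_mM: float | np.ndarray, cmc_mM: float, v_shyd: float):
    """φ = Vshyd·N_A·10⁻²⁴·(c − CMC)/1000, clipped at 0 below the CMC."""
    x = np.maximum(np.asarray(c_mM, dtype=float) - cmc_mM, 0.0) * 1e-3
    return v_shyd * NM3_PER_MOLECULE_TO_PER_MOLAR * x


def fit_virial(
    series: TitrationSeries,
    cmc_mM: float,
    nu: float,
    free_intercept: bool = False,
) -> ViscosityFit:
    """Fit ηr − 1 = p₁x + p₂x², x = (c − CMC) in mol/L, intercept fixed at 0.

    The intercept is pinned by the model (ηr → 1 at the CMC), not the data;
    ``free_intercept=True`` releases it for diagnostics only (the reported
    p₁, p₂ then come from the 3-parameter fit).
    """
    if series.response_kind is not ResponseKind.RELATIVE_VISCOSITY:
        raise DomainError(
            f"expected relative viscosities, got {series.response_kind.value} "
            "(convert efflux times first)"
        )
    if nu < NU_SPHERE:
        raise DomainError(f"shape factor must be ≥ 2.5, got {nu}")
    above = series.concentration > cmc_mM
    if int(np.sum(above)) < 4:
        raise InsufficientDataError("need ≥ 4 points above the CMC for the virial fit")
    x = (series.concentration[above] - cmc_mM) * 1e-3  # mol/L
    y = series.response[above] - 1.0

    cols = [x, x**2]
    if free_intercept:
        cols.insert(0, np.ones_like(x))
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    p1, p2 = (float(coef[-2]), float(coef[-1]))

    flags: list[str] = []
    if np.allclose(series.response, 1.0):
        p1, p2 = 0.0, 0.0
        flags.append("no micellar contribution")
    if p1 <= 0 and "no micellar contribution" not in flags:
        flags.append("nonphysical p1")

    v_shyd = p1 / (nu * NM3_PER_MOLECULE_TO_PER_MOLAR)
    k1 = p2 / p1**2 if p1 > 0 else float("nan")
    logger.info("virial fit: p1=%.6g p2=%.6g Vshyd=%.6g nm³ k1=%.4g rss=%.3g",
                p1, p2, v_shyd, k1, rss)
    return ViscosityFit(
        p1=p1, p2=p2, k1=k1, nu=nu, v_shyd=v_shyd, c1_mM=cmc_mM,
        rss=rss, n_points=int(np.sum(above)), flags=tuple(flags),
    )


def equivalent_prolate_axial_ratio(axial_ratio: float) -> float:
    """J = (L/d)·[2/(3 − d/L)]^½ — the prolate ellipsoid of equal length and
    volume as a hemisphere-capped rod; J = 1 exactly at L/d = 1."""
    if axial_ratio < 1:
        raise DomainError("axial ratio L/d must be ≥ 1")
    return axial_ratio * np.sqrt(2.0 / (3.0 - 1.0 / axial_ratio))


def nu_from_j(j: float) -> float:
    """Shape factor from the equivalent prolate axial ratio."""
    if j < 1:
        raise DomainError("equivalent axial ratio J must be ≥ 1")
    if j <= J_CROSSOVER:
        nu_short = NU_SPHERE + 0.407 * (j - 1.0) ** 1.508
        if j == J_CROSSOVER:
            nu_long = _nu_long_rod(j)
            logger.info("J = 15 crossover: short-rod %.4f vs long-rod %.4f "
                        "(short-rod reported)", nu_short, nu_long)
        return nu_short
    return _nu_long_rod(j)


def _nu_long_rod(j: float) -> float:
    l2j = np.log(2.0 * j)
    return 1.6 + (j**2 / 15.0) * (1.0 / (l2j - 1.5) + 3.0 / (l2j - 0.5))


def j_from_nu(nu: float) -> float:
    """Invert the short-rod formula: J = 1 + ((ν − 2.5)/0.407)^(1/1.508)."""
    if nu < NU_SPHERE:
        raise DomainError(f"shape factor must be ≥ 2.5, got {nu}")
    return 1.0 + ((nu - NU_SPHERE) / 0.407) ** (1.0 / 1.508)


def shape_factor(axial_ratio: float) -> ShapeModel:
    """Shape factor ν of a hemisphere-capped cylindrical micelle of given L/d."""
    j = equivalent_prolate_axial_ratio(axial_ratio)
    nu = nu_from_j(j)
    if j == 1.0:
        regime = MicelleRegime.SPHERE
    elif j <= J_CROSSOVER:
        regime = MicelleRegime.SHORT_ROD
    else:
        regime = MicelleRegime.LONG_ROD
    return ShapeModel(axial_ratio=float(axial_ratio), j=float(j), nu=float(nu),
                      regime=regime)


def hydration_budget(
    v_shyd: float,
    spec: SurfactantSpec,
    solvent: SolventSpec,
    v_water_total_reference: float | None = None,
    scenario: HydrationScenario | str = HydrationScenario.DIRECT,
) -> HydrationBudget:
    """Partition the hydrated volume into molecule + water + cosolvent.

    Without a reference the whole solvation shell is counted as water.
    With ``v_water_total_reference`` (the water shell from the plain-water
    condition, assumed unchanged by the cosolvent), the excess is assigned
    to cosolvent molecules.  Water counts round to the nearest integer and
    cosolvent counts to one decimal; the volume identity
    v_shyd = v_molecule + v_water_total + v_cosolvent_total holds exactly
    before rounding.
    """
    if v_shyd < spec.molecular_volume:
        raise DomainError(
            f"hydrated volume {v_shyd} nm³ is below the molecular volume "
            f"{spec.molecular_volume} nm³"
        )
    v_mol = spec.molecular_volume
    flags: list[str] = []
    if v_water_total_reference is None:
        v_water_total = v_shyd - v_mol
        v_cosolvent_total = 0.0
        n_cosolvent = 0.0
    else:
        v_water_total = float(v_water_total_reference)
        v_cosolvent_total = v_shyd - v_mol - v_water_total
        if v_cosolvent_total < 0:
            warnings.warn("dehydration relative to reference: cosolvent count floored at 0",
                          stacklevel=2)
            flags.append("dehydration relative to reference")
            v_cosolvent_total = 0.0
            v_water_total = v_shyd - v_mol
        n_cosolvent = cosolvent_count(v_cosolvent_total, solvent.cosolvent_molecular_volume)
    n_water = int(round(v_water_total / solvent.water_molecular_volume))
    return HydrationBudget(
        v_shyd=v_shyd, v_molecule=v_mol,
        v_water_total=v_water_total, n_water=n_water,
        v_cosolvent_total=v_cosolvent_total, n_cosolvent=n_cosolvent,
        scenario=HydrationScenario(scenario), flags=tuple(flags),
    )


def cosolvent_count(v_cosolvent_total: float, v_cosolvent_single: float) -> float:
    """Cosolvent molecules per surfactant, one-decimal reporting convention."""
    if v_cosolvent_single <= 0:
        raise DomainError("single-molecule cosolvent volume must be positive")
    if v_cosolvent_total < 0:
        raise DomainError("total cosolvent volume must be ≥ 0")
    return round(v_cosolvent_total / v_cosolvent_single, 1)
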