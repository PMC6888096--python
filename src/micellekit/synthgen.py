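"""Seeded forward simulators for the four titration measurements.

Each generator produces data with exactly the structure its paired analysis
stage assumes, so that at zero noise every estimator inverts its generator
exactly, and under noise the generators provide ground truth for
Monte-Carlo recovery tests:

* conductivity — piecewise-linear in concentration with a slope break at
  the CMC (post/pre slope ratio = α), optionally smoothed over a finite
  transition width (softplus blend) to emulate the gradual break seen at
  high cosolvent concentration;
* surface tension — linear descent in log₁₀ C down to the CMC, constant
  plateau above;
* pyrene I1/I3 — a Langmuir-type bound fraction above the CMC interpolating
  between the aqueous and micellar limiting ratios, optionally rendered as
  full two-band Gaussian emission spectra;
* relative viscosity — the second-order virial expansion in the micellar
  volume fraction.

Default truth parameters are the measured APFO-in-water conditions: CMC
26.5 mM, α 0.47, tension slope −29.6 mN/m per decade (plateau ≈ 18 mN/m),
ν 2.97, Vshyd 0.710 nm³.  Noise is independent Gaussian per channel:
0.5% relative on conductivity, 0.3 mN/m on tension, 0.01 on the ratio, and
0.002 on ηr (the viscometer's ±0.2% efflux-time reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fluorimetry import EmissionSpectrum
from .io import DomainError, ResponseKind, TitrationSeries
from .viscometry import micellar_volume_fraction


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters shared by all four generators."""

    cmc: float = 26.5            # mM
    alpha: float = 0.47
    kappa0: float = 2.0          # background conductivity, µS/cm
    s1: float = 50.0             # pre-CMC conductivity slope, µS cm⁻¹ mM⁻¹
    gamma0: float = 60.0         # surface tension at 1 mM, mN/m
    tension_slope: float = -29.6  # dγ/dlogC, mN/m per decade
    plateau_gamma: float | None = None  # derived from (gamma0, slope, cmc) if None
    ratio_water: float = 1.8     # I1/I3 aqueous baseline
    ratio_micelle: float = 1.2   # I1/I3 fully-bound limit
    partition_k: float = 0.2     # pyrene binding constant, per mM above CMC
    nu: float = 2.97             # micelle shape factor
    v_shyd: float = 0.710        # hydrated molecular volume, nm³
    k1: float = 1.0              # pairwise hydrodynamic coefficient
    transition_width: float = 0.0  # mM; 0 → sharp conductivity break
    noise_conductivity_rel: float = 0.005
    noise_tension: float = 0.3   # mN/m, absolute
    noise_ratio: float = 0.01    # absolute
    noise_eta: float = 0.002     # absolute
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cmc <= 0:
            raise DomainError("cmc must be positive")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")
        if self.ratio_water <= self.ratio_micelle:
            raise DomainError("ratio_water must exceed ratio_micelle")
        if self.partition_k <= 0:
            raise DomainError("partition_k must be positive")
        if self.transition_width < 0:
            raise DomainError("transition_width must be ≥ 0")
        for name in ("noise_conductivity_rel", "noise_tension", "noise_ratio", "noise_eta"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be ≥ 0")

    def noiseless(self) -> "TruthParams":
        return replace(self, noise_conductivity_rel=0.0, noise_tension=0.0,
                       noise_ratio=0.0, noise_eta=0.0)

    @property
    def derived_plateau_gamma(self) -> float:
        """Plateau value continuous with the descending branch at the CMC."""
        return self.gamma0 + self.tension_slope * np.log10(self.cmc)


#: default concentration grids mirroring the measured ranges
CONDUCTIVITY_GRID = np.arange(1.0, 50.1, 1.0)         # 0–50 mM range, 1-mM steps
TENSION_GRID = np.geomspace(2.0, 60.0, 16)
PYRENE_GRID = np.geomspace(1.0, 200.0, 24)            # 1–200 mM range
VISCOSITY_GRID = np.arange(30.0, 151.0, 10.0)


def _rng(params: TruthParams, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(params.seed if seed is None else seed)


def gen_conductivity(
    params: TruthParams,
    concentrations: np.ndarray | None = None,
    seed: int | None = None,
    temperature_c: float = 24.0,
) -> TitrationSeries:
    """κ(C): slope s1 below the CMC, α·s1 above, continuous at the break.

    With ``transition_width`` w > 0 the slope change is blended smoothly,
    κ(C) = κ0 + s1·C − s1(1−α)·w·ln(1 + e^((C−cmc)/w)), which tends to the
    sharp piecewise line as w → 0.
    """
    c = np.asarray(CONDUCTIVITY_GRID if concentrations is None else concentrations,
                   dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise DomainError("concentrations must be positive and ascending")
    w = params.transition_width
    if w == 0:
        kappa = params.kappa0 + params.s1 * np.minimum(c, params.cmc) \
            + params.alpha * params.s1 * np.maximum(c - params.cmc, 0.0)
    else:
        kappa = (params.kappa0 + params.s1 * c
                 - params.s1 * (1.0 - params.alpha) * w
                 * np.logaddexp(0.0, (c - params.cmc) / w))
    if params.noise_conductivity_rel > 0:
        rng = _rng(params, seed)
        kappa = kappa * (1.0 + params.noise_conductivity_rel
                         * rng.standard_normal(len(c)))
    return TitrationSeries(concentration=c, response=kappa,
                           response_kind=ResponseKind.CONDUCTIVITY,
                           temperature_c=temperature_c)


def gen_tension(
    params: TruthParams,
    concentrations: np.ndarray | None = None,
    seed: int | None = None,
    temperature_c: float = 24.0,
) -> TitrationSeries:
    """γ(C): gamma0 + slope·log₁₀C below the CMC, plateau above."""
    c = np.asarray(TENSION_GRID if concentrations is None else concentrations,
                   dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise DomainError("concentrations must be positive and ascending")
    descending = params.gamma0 + params.tension_slope * np.log10(c)
    plateau = params.plateau_gamma
    if plateau is None:
        plateau = params.derived_plateau_gamma
    elif plateau > params.derived_plateau_gamma + 1e-9:
        raise DomainError(
            "plateau_gamma lies above the descending branch at the CMC: "
            "inconsistent parameters"
        )
    gamma = np.where(c <= params.cmc, descending, plateau)
    if params.noise_tension > 0:
        rng = _rng(params, seed)
        gamma = gamma + params.noise_tension * rng.standard_normal(len(c))
    return TitrationSeries(concentration=c, response=gamma,
                           response_kind=ResponseKind.SURFACE_TENSION,
                           temperature_c=temperature_c)


def bound_fraction(c_mM: np.ndarray, cmc: float, k: float) -> np.ndarray:
    """Pyrene micelle-bound fraction: 0 below the CMC, Langmuir-type above."""
    excess = np.maximum(np.asarray(c_mM, dtype=float) - cmc, 0.0)
    return k * excess / (1.0 + k * excess)


def gen_pyrene(
    params: TruthParams,
    concentrations: np.ndarray | None = None,
    seed: int | None = None,
    full_spectra: bool = False,
    temperature_c: float = 22.0,
    wavelength_grid: np.ndarray | None = None,
):
    """I1/I3 titration, or full two-band emission spectra when requested.

    The ratio is the bound-fraction mixture of the aqueous and micellar
    limits.  Spectra are two Gaussian bands (373 and 383 nm centers,
    3 nm width); band heights solve a 2×2 system so the window peak heights
    realize the target ratio despite band overlap.
    """
    c = np.asarray(PYRENE_GRID if concentrations is None else concentrations,
                   dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise DomainError("concentrations must be positive and ascending")
    f = bound_fraction(c, params.cmc, params.partition_k)
    ratio = (1.0 - f) * params.ratio_water + f * params.ratio_micelle
    rng = _rng(params, seed)
    if not full_spectra:
        if params.noise_ratio > 0:
            ratio = ratio + params.noise_ratio * rng.standard_normal(len(c))
        return TitrationSeries(concentration=c, response=ratio,
                               response_kind=ResponseKind.I1I3,
                               temperature_c=temperature_c)

    wl = np.arange(360.0, 400.01, 0.25) if wavelength_grid is None else \
        np.asarray(wavelength_grid, dtype=float)
    band1 = np.exp(-0.5 * ((wl - 373.0) / 3.0) ** 2)
    band3 = np.exp(-0.5 * ((wl - 383.0) / 3.0) ** 2)
    g = np.exp(-0.5 * (10.0 / 3.0) ** 2)  # cross-talk of one band at the other center
    spectra = []
    for ci, ri in zip(c, ratio):
        # peak heights: h1 + g·h3 = ri, g·h1 + h3 = 1
        det = 1.0 - g * g
        h1 = (ri - g) / det
        h3 = (1.0 - g * ri) / det
        intensity = h1 * band1 + h3 * band3
        if params.noise_ratio > 0:
            intensity = intensity * (1.0 + params.noise_ratio
                                     * rng.standard_normal(len(wl)))
        spectra.append(EmissionSpectrum(wavelength=wl, intensity=intensity,
                                        label_mM=float(ci)))
    return spectra


def gen_viscosity(
    params: TruthParams,
    concentrations: np.ndarray | None = None,
    seed: int | None = None,
    temperature_c: float = 20.0,
) -> TitrationSeries:
    """ηr(C) = 1 + νφ + k₁(νφ)² with φ = Vshyd·N_A·10⁻²⁴·(C − CMC)/1000."""
    c = np.asarray(VISCOSITY_GRID if concentrations is None else concentrations,
                   dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise DomainError("concentrations must be positive and ascending")
    phi = micellar_volume_fraction(c, params.cmc, params.v_shyd)
    eta_r = 1.0 + params.nu * phi + params.k1 * (params.nu * phi) ** 2
    if params.noise_eta > 0:
        rng = _rng(params, seed)
        eta_r = eta_r + params.noise_eta * rng.standard_normal(len(c))
    return TitrationSeries(concentration=c, response=eta_r,
                           response_kind=ResponseKind.RELATIVE_VISCOSITY,
                           temperature_c=temperature_c)


def gen_all(params: TruthParams, seed: int | None = None) -> dict[str, TitrationSeries]:
    """One titration series of each kind on the default grids."""
    base = params.seed if seed is None else seed
    return {
        "conductivity": gen_conductivity(params, seed=base),
        "tension": gen_tension(params, seed=base + 1),
        "pyrene": gen_pyrene(params, seed=base + 2),
        "viscosity": gen_viscosity(params, seed=base + 3),
    }
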