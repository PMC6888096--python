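"""Domain types, physical constants, units, and file I/O.

Concentration is millimolar (mM) everywhere at the interface; operations
that need SI convert internally.  CSV files are comma-separated with one
header row, ``.`` decimals, and ``#`` comment lines.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger("micellekit")

# Gas constant, J mol^-1 K^-1
R = 8.314
# Avogadro number, mol^-1
AVOGADRO = 6.022e23

#: mol/L per mM
MM_TO_MOLAR = 1e-3


class MicelleKitError(Exception):
    """Base class for all package errors."""


class ParseError(MicelleKitError):
    """A file could not be parsed; message names the offending row."""


class InsufficientDataError(MicelleKitError):
    """Too few points for the requested analysis."""


class DomainError(MicelleKitError, ValueError):
    """An argument is outside its physical domain."""


class ResponseKind(str, enum.Enum):
    CONDUCTIVITY = "conductivity"          # µS/cm
    SURFACE_TENSION = "surface_tension"    # mN/m
    I1I3 = "i1i3"                          # dimensionless
    EFFLUX_TIME = "efflux_time"            # s
    RELATIVE_VISCOSITY = "relative_viscosity"  # dimensionless


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert °C to K; rejects temperatures below absolute zero."""
    if t_celsius < -273.15:
        raise DomainError(f"temperature {t_celsius} °C is below absolute zero")
    return t_celsius + 273.15


def mM_to_molar(c_mM: float) -> float:
    """mM → mol/L."""
    return c_mM * MM_TO_MOLAR


def molar_to_mM(c_molar: float) -> float:
    """mol/L → mM."""
    return c_molar / MM_TO_MOLAR


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration: response measured at increasing concentration.

    Parameters
    ----------
    concentration
        Surfactant concentrations in mM, strictly increasing.
    response
        Measured values (units depend on ``response_kind``).
    response_kind
        Which observable the response column holds.
    temperature_c
        Measurement temperature in °C, in [0, 100).
    """

    concentration: np.ndarray
    response: np.ndarray
    response_kind: ResponseKind
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "response_kind", ResponseKind(self.response_kind))
        if c.ndim != 1 or r.shape != c.shape:
            raise DomainError("concentration and response must be 1-D and equal length")
        if len(c) < 2:
            raise DomainError("a titration series needs at least 2 points")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(r))):
            raise DomainError("non-finite value in titration series")
        if np.any(np.diff(c) <= 0):
            raise DomainError("concentrations must be strictly increasing")
        if not (0.0 <= self.temperature_c < 100.0):
            raise DomainError(f"temperature {self.temperature_c} °C outside [0, 100)")

    def __len__(self) -> int:
        return len(self.concentration)

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    def require_points(self, n: int) -> "TitrationSeries":
        if len(self) < n:
            raise InsufficientDataError(
                f"{self.response_kind.value} analysis needs ≥ {n} points, got {len(self)}"
            )
        return self

    def scaled(self, factor: float) -> "TitrationSeries":
        return replace(self, response=self.response * factor)


class TailChemistry(str, enum.Enum):
    FLUOROCARBON = "fluorocarbon"
    HYDROCARBON = "hydrocarbon"


@dataclass(frozen=True)
class SurfactantSpec:
    """Identity and molecular descriptors of a surfactant.

    ``molecular_volume`` is the anhydrous molecular volume in nm³;
    ``ion_valences`` is (surfactant ion, counterion); the Gibbs prefactor n
    defaults to 2 when both are monovalent.
    """

    name: str
    tail_carbons: int
    tail_chemistry: TailChemistry
    molecular_volume: float  # nm³
    ion_valences: tuple[int, int] = (-1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tail_chemistry", TailChemistry(self.tail_chemistry))
        if self.tail_carbons < 1:
            raise DomainError("tail_carbons must be ≥ 1")
        if self.molecular_volume <= 0:
            raise DomainError("molecular_volume must be positive")
        if 0 in self.ion_valences:
            raise DomainError("ion valences must be nonzero")

    @property
    def default_n_prefactor(self) -> int:
        """Gibbs prefactor: 2 for 1:1 ionic surfactants."""
        if abs(self.ion_valences[0]) == 1 and abs(self.ion_valences[1]) == 1:
            return 2
        return 1


@dataclass(frozen=True)
class SolventSpec:
    """Aqueous solvent with an optional cosolvent (e.g. urea)."""

    cosolvent_name: str = "urea"
    cosolvent_molarity: float = 0.0      # mol/L
    cosolvent_molecular_volume: float = 0.075  # nm³ (urea)
    water_molecular_volume: float = 0.030      # nm³

    def __post_init__(self) -> None:
        if self.cosolvent_molarity < 0:
            raise DomainError("cosolvent molarity must be ≥ 0")
        if self.cosolvent_molecular_volume <= 0 or self.water_molecular_volume <= 0:
            raise DomainError("molecular volumes must be positive")


# Bundled surfactants: APFO (C7F15-COO NH4) and SDS (C12H25-OSO3 Na).
APFO = SurfactantSpec(
    name="APFO",
    tail_carbons=7,
    tail_chemistry=TailChemistry.FLUOROCARBON,
    molecular_volume=0.376,
    ion_valences=(-1, 1),
)
SDS = SurfactantSpec(
    name="SDS",
    tail_carbons=12,
    tail_chemistry=TailChemistry.HYDROCARBON,
    molecular_volume=0.410,
    ion_valences=(-1, 1),
)
WATER = SolventSpec(cosolvent_molarity=0.0)
UREA_4M = SolventSpec(cosolvent_molarity=4.0)

BUNDLED_SURFACTANTS = {"apfo": APFO, "sds": SDS}


def read_titration(
    path: str | Path,
    response_kind: ResponseKind | str,
    temperature_c: float = 25.0,
) -> TitrationSeries:
    """Read a two-column titration CSV (concentration_mM, response).

    Rows are sorted by concentration; duplicate concentrations are averaged
    with a warning.  Non-numeric cells raise :class:`ParseError` naming the
    row.  Point-count requirements are enforced by the analysis stages, not
    the reader.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col!r}, data row {bad[0] + 1}"
            )
        df[col] = converted
    df = df.dropna()
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 usable rows")
    df.columns = ["concentration", "response"]
    if df["concentration"].duplicated().any():
        warnings.warn(f"{path}: duplicate concentrations averaged", stacklevel=2)
        df = df.groupby("concentration", as_index=False)["response"].mean()
    df = df.sort_values("concentration")
    return TitrationSeries(
        concentration=df["concentration"].to_numpy(),
        response=df["response"].to_numpy(),
        response_kind=ResponseKind(response_kind),
        temperature_c=temperature_c,
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    """Write a series in the CSV dialect :func:`read_titration` reads."""
    df = pd.DataFrame(
        {"concentration_mM": series.concentration, series.response_kind.value: series.response}
    )
    df.to_csv(path, index=False)


# --- canonical JSON report serialization ---------------------------------

def _canonical(obj: Any) -> Any:
    """Make a report JSON-stable: sorted keys come from json.dumps; floats
    are rounded through repr so read→write round-trips byte-identically."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    if isinstance(obj, enum.Enum):
        return obj.value
    return obj


def dumps_report(report: dict) -> str:
    """Serialize a report with canonical key order and float formatting."""
    return json.dumps(_canonical(report), sort_keys=True, indent=1) + "\n"


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(dumps_report(report))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
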