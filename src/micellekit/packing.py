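"""Fluorocarbon tail geometry and critical-packing-parameter shape inference.

The tail volume and extended length of a linear perfluorinated chain with
``n_c`` carbons follow a group-additivity model: the chain has (n_c − 1) CF₂
groups (41.6 ų each) and one terminal CF₃ (84.0 ų), giving

    V = 41.6 n_c + 42.4   [ų]
    l = 1.3 n_c + 2.04    [Å]

The critical packing parameter CPP = V₀ / (A_min · l_c) classifies the
preferred aggregate curvature: sphere (≤ 1/3), cylinder (1/3–1/2),
bilayer (1/2–1), inverted (> 1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io import DomainError

#: CF2 group volume, ų
CF2_VOLUME = 41.6
#: CF3 group volume, ų
CF3_VOLUME = 84.0

#: half-width of the "near a shape boundary" annotation band
BOUNDARY_TOL = 0.01

_SPHERE_MAX = 1.0 / 3.0
_CYLINDER_MAX = 0.5
_BILAYER_MAX = 1.0


class ShapeClass(str, enum.Enum):
    SPHERE = "sphere"
    CYLINDER = "cylinder"
    BILAYER = "bilayer"
    INVERTED = "inverted"


@dataclass(frozen=True)
class TailGeometry:
    """Hydrophobic tail volume (ų), extended length (Å), and carbon count."""

    volume: float
    length: float
    carbons: int

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.length <= 0:
            raise DomainError("tail volume and length must be positive")


@dataclass(frozen=True)
class PackingResult:
    """CPP with its shape classification.

    ``boundary`` is set when the CPP sits within 0.01 of a class threshold,
    recording that the deterministic classification is geometrically
    ambiguous (e.g. 0.34 is cylindrical by the strict 1/3 cut but close to
    the spherical range).
    """

    cpp: float
    shape_class: ShapeClass
    amin_used: float  # Å²
    boundary: bool = False

    @property
    def cpp_display(self) -> float:
        """Two-decimal display convention."""
        return round(self.cpp, 2)


def fluorotail_volume(n_c: int) -> float:
    """Volume (ų) of a linear fluorocarbon tail with ``n_c`` carbons."""
    if int(n_c) != n_c or n_c < 1:
        raise DomainError(f"carbon count must be an integer ≥ 1, got {n_c}")
    return CF2_VOLUME * n_c + (CF3_VOLUME - CF2_VOLUME)


def fluorotail_length(n_c: int) -> float:
    """Extended length (Å) of a linear fluorocarbon tail with ``n_c`` carbons."""
    if int(n_c) != n_c or n_c < 1:
        raise DomainError(f"carbon count must be an integer ≥ 1, got {n_c}")
    return 1.3 * n_c + 2.04


def fluorocarbon_tail(n_c: int) -> TailGeometry:
    """Group-additivity geometry of a linear fluorocarbon tail."""
    return TailGeometry(
        volume=fluorotail_volume(n_c), length=fluorotail_length(n_c), carbons=int(n_c)
    )


def classify_cpp(cpp: float) -> ShapeClass:
    """Shape class from the standard curvature bands (exact 1/3, 1/2, 1)."""
    if cpp <= _SPHERE_MAX:
        return ShapeClass.SPHERE
    if cpp <= _CYLINDER_MAX:
        return ShapeClass.CYLINDER
    if cpp <= _BILAYER_MAX:
        return ShapeClass.BILAYER
    return ShapeClass.INVERTED


def packing_parameter(volume: float, amin: float, length: float) -> PackingResult:
    """Critical packing parameter CPP = volume / (amin · length).

    Parameters are the tail volume in ų, the headgroup area in Å², and the
    extended tail length in Å.  The CPP is kept at full precision; rounding
    is a display concern only (:attr:`PackingResult.cpp_display`).
    """
    if volume <= 0 or amin <= 0 or length <= 0:
        raise DomainError("volume, amin, and length must all be positive")
    cpp = volume / (amin * length)
    boundary = any(
        abs(cpp - b) <= BOUNDARY_TOL for b in (_SPHERE_MAX, _CYLINDER_MAX, _BILAYER_MAX)
    )
    return PackingResult(
        cpp=cpp, shape_class=classify_cpp(cpp), amin_used=amin, boundary=boundary
    )
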