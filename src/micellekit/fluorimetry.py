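"""Pyrene vibronic-band analysis and the intersection CMC criterion.

Monomeric pyrene's emission fine structure reports the polarity of its
microenvironment: the ratio of the first (~373 nm) to third (383 nm)
vibronic band intensities, I1/I3, is ~1.8 in water and drops toward ~1.2
when the probe partitions into micelles.  Plotting I1/I3 against surfactant
concentration therefore shows a plateau at the aqueous value followed by a
sigmoidal decrease across the CMC; the CMC is read as the intersection of a
line fitted to the low-concentration plateau with a line fitted to the
steepest part of the decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import (
    DomainError,
    InsufficientDataError,
    MicelleKitError,
    ResponseKind,
    TitrationSeries,
    logger,
)

#: wavelength search window for the first vibronic band, nm
I1_WINDOW = (370.0, 376.0)
#: wavelength search window for the third vibronic band (383 nm anchor), nm
I3_WINDOW = (380.0, 386.0)

#: points on either side of the steepest descent that enter the descent line
DESCENT_HALF_WIDTH = 2


class NoCmcError(MicelleKitError):
    """The ratio curve shows no plateau-then-decrease signature."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """A pyrene emission spectrum labelled by sample concentration (mM)."""

    wavelength: np.ndarray  # nm, ascending
    intensity: np.ndarray   # arbitrary units, ≥ 0
    label_mM: float = float("nan")

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise DomainError("wavelength and intensity must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelength grid must be strictly ascending")
        if wl[0] > 365.0 or wl[-1] < 395.0:
            raise DomainError("spectrum must cover at least 365–395 nm")
        if not np.all(np.isfinite(it)):
            raise DomainError("intensities must be finite")
        if np.all(it == 0):
            raise DomainError("spectrum is identically zero")


@dataclass(frozen=True)
class VibronicRatios:
    i1: float
    i3: float
    ratio: float
    lambda1: float
    lambda3: float
    flags: tuple[str, ...] = ()


def _window_peak(spec: EmissionSpectrum, window: tuple[float, float]):
    mask = (spec.wavelength >= window[0]) & (spec.wavelength <= window[1])
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise DomainError(f"spectrum has no samples in window {window}")
    sub = spec.intensity[idx]
    k = idx[int(np.argmax(sub))]
    at_edge = k == idx[0] or k == idx[-1]
    return float(spec.intensity[k]), float(spec.wavelength[k]), at_edge


def vibronic_ratio(
    spectrum: EmissionSpectrum,
    i1_window: tuple[float, float] = I1_WINDOW,
    i3_window: tuple[float, float] = I3_WINDOW,
) -> VibronicRatios:
    """I1/I3 from the band maxima inside the two search windows.

    If a window's maximum sits on its edge (no interior local maximum) the
    edge value is used and the result is flagged.
    """
    i1, l1, edge1 = _window_peak(spectrum, i1_window)
    i3, l3, edge3 = _window_peak(spectrum, i3_window)
    if i1 <= 0 or i3 <= 0:
        raise DomainError("band intensities must be positive to form I1/I3")
    flags = []
    if edge1:
        flags.append("i1 window edge")
    if edge3:
        flags.append("i3 window edge")
    return VibronicRatios(i1=i1, i3=i3, ratio=i1 / i3, lambda1=l1, lambda3=l3,
                          flags=tuple(flags))


def normalize_by_i1(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Divide the whole spectrum by the first-band intensity (value 1 at λ1)."""
    i1, _, _ = _window_peak(spectrum, I1_WINDOW)
    if i1 <= 0:
        raise DomainError("cannot normalize: first-band intensity is not positive")
    return replace(spectrum, intensity=spectrum.intensity / i1)


def ratios_from_spectra(spectra: list[EmissionSpectrum], temperature_c: float = 22.0,
                        **windows) -> TitrationSeries:
    """Collapse labelled spectra into an I1/I3 titration series."""
    pairs = sorted(
        ((s.label_mM, vibronic_ratio(s, **windows).ratio) for s in spectra),
        key=lambda p: p[0],
    )
    conc, ratio = zip(*pairs)
    return TitrationSeries(
        concentration=np.array(conc), response=np.array(ratio),
        response_kind=ResponseKind.I1I3, temperature_c=temperature_c,
    )


@dataclass(frozen=True)
class RatioCmcFit:
    cmc: float                       # mM
    plateau_line: tuple[float, float]   # (slope, intercept) of the plateau fit
    descent_line: tuple[float, float]   # (slope, intercept) of the descent fit
    plateau_indices: tuple[int, ...]
    descent_indices: tuple[int, ...]
    flags: tuple[str, ...] = ()


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2:
        raise InsufficientDataError("need ≥ 2 points for a line")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def cmc_from_ratio_curve(
    series: TitrationSeries,
    k: int = DESCENT_HALF_WIDTH,
    variant: str = "lower_plateau",
    plateau_rel_spread: float = 0.05,
    fit_plateau_slope: bool = False,
) -> RatioCmcFit:
    """CMC from the intersection of the plateau line and the descent line.

    The default (and recommended) variant intersects the low-concentration
    plateau with the steepest-descent line; ``variant="upper_plateau"``
    intersects the descent with the terminal plateau instead.

    The descent line is fitted to the points within ``k`` of the steepest
    drop between adjacent samples (ties resolved to the middle of the tied
    run); the plateau is the maximal initial (or terminal) run whose ratio
    spread is within ``plateau_rel_spread`` of the curve's full range, and
    its line is horizontal by default (``fit_plateau_slope=True`` fits a
    shallow slope instead).
    """
    if series.response_kind is not ResponseKind.I1I3:
        raise DomainError(f"expected an I1/I3 series, got {series.response_kind.value}")
    series.require_points(6)
    conc, resp = series.concentration, series.response

    n = len(conc)
    third = max(1, n // 3)
    if np.mean(resp[:third]) <= np.mean(resp[-third:]):
        raise NoCmcError("ratio curve does not decrease: no plateau-then-descent signature")

    # Steepest descent located by the largest undivided drop between adjacent
    # samples: on log-spaced grids, per-mM slopes between closely spaced
    # low-concentration points are noise-dominated, raw drops are not.
    diffs = np.diff(resp)
    steepest = np.min(diffs)
    tied = np.flatnonzero(np.isclose(diffs, steepest, rtol=1e-9, atol=1e-12))
    i_star = int(tied[len(tied) // 2])  # middle of the tied run

    spread_tol = plateau_rel_spread * float(np.ptp(resp))

    # plateau run
    if variant == "lower_plateau":
        end = 0
        while end + 1 < n and np.ptp(resp[: end + 2]) <= spread_tol:
            end += 1
        plateau_idx = np.arange(0, end + 1)
    elif variant == "upper_plateau":
        start = n - 1
        while start - 1 >= 0 and np.ptp(resp[start - 1:]) <= spread_tol:
            start -= 1
        plateau_idx = np.arange(start, n)
    else:
        raise DomainError(f"unknown variant {variant!r}")

    # Descent run around the steepest finite difference.  The window is
    # clipped at the plateau edge but keeps the edge point itself: the last
    # plateau point anchors the descent line at the kink without letting
    # plateau-interior points flatten it.
    lo = max(0, i_star - k)
    hi = min(n - 1, i_star + 1 + k)
    if variant == "lower_plateau" and len(plateau_idx):
        lo = min(max(lo, int(plateau_idx[-1])), i_star)
    if variant == "upper_plateau" and len(plateau_idx):
        hi = max(min(hi, int(plateau_idx[0])), i_star + 1)
    descent_idx = np.arange(lo, hi + 1)
    if len(descent_idx) < 2:
        raise InsufficientDataError("descent window too small to define a line")

    flags: list[str] = []
    if fit_plateau_slope and len(plateau_idx) >= 2:
        p_slope, p_int = _fit_line(conc[plateau_idx], resp[plateau_idx])
    else:
        # default: horizontal plateau line through the plateau mean
        p_slope, p_int = 0.0, float(np.mean(resp[plateau_idx]))
        if len(plateau_idx) < 2:
            flags.append("single-point plateau")
    d_slope, d_int = _fit_line(conc[descent_idx], resp[descent_idx])

    if np.isclose(d_slope, p_slope):
        raise NoCmcError("plateau and descent lines are parallel")
    cmc = (p_int - d_int) / (d_slope - p_slope)
    if not (conc[0] <= cmc <= conc[-1]):
        flags.append("extrapolated intersection")

    logger.info("I1/I3 CMC: %.4g mM (plateau n=%d, descent n=%d, variant=%s)",
                cmc, len(plateau_idx), len(descent_idx), variant)
    return RatioCmcFit(
        cmc=float(cmc),
        plateau_line=(p_slope, p_int),
        descent_line=(d_slope, d_int),
        plateau_indices=tuple(int(i) for i in plateau_idx),
        descent_indices=tuple(int(i) for i in descent_idx),
        flags=tuple(flags),
    )
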