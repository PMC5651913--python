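"""Per-photostate absorption spectra and spectral arithmetic.

Phytochromes photo-interconvert between a red-absorbing Pr state and a
far-red-absorbing Pfr state; a lumped "Bleached" photoproduct can also
accumulate.  Each state's visible absorption is modelled as a sum of
Gaussian bands (the red/far-red Q band and, when the grid reaches it, the
blue Soret band).  Gaussians are a convention: the source data report only
band maxima, and a smooth unimodal closed form is all the downstream
kinetics need.

Absorbance is treated as path-normalized (samples are conventionally
diluted so the Pr Q-band maximum is 0.4 AU), so spectra carry no
path-length field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Band",
    "StateSpectrum",
    "Spectrum",
    "IsosbesticResult",
    "evaluate_state_spectrum",
    "mixture_spectrum",
    "difference_spectrum",
    "find_extrema",
    "isosbestic_points",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    Parameters
    ----------
    center : float
        Band maximum in nm.
    width : float
        Gaussian standard deviation in nm; must be positive.
    amplitude : float
        Peak absorbance in AU; must be non-negative.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")


def _as_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return g


@dataclass(frozen=True)
class Spectrum:
    """A sampled absorbance spectrum: wavelengths (nm) and values (AU)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", _as_grid(self.grid))
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("grid and values must have identical length")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class StateSpectrum:
    """Absorption spectrum of one photostate as a sum of Gaussian bands."""

    state_label: str
    bands: tuple[Band, ...]
    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "grid", _as_grid(self.grid))


def _gaussian_sum(bands: Sequence[Band], x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for b in bands:
        out += b.amplitude * np.exp(-((x - b.center) ** 2) / (2.0 * b.width**2))
    return out


def evaluate_state_spectrum(s: StateSpectrum) -> Spectrum:
    """Evaluate a state's band model on its wavelength grid."""
    return Spectrum(s.grid, _gaussian_sum(s.bands, s.grid))


def mixture_spectrum(
    states: Sequence[StateSpectrum],
    occupancies: Sequence[float],
    *,
    tol: float = 1e-8,
) -> Spectrum:
    """Beer–Lambert mixture: occupancy-weighted sum of state spectra.

    All states must share one wavelength grid, occupancies must be
    non-negative and sum to 1 within ``tol``.
    """
    if len(states) == 0 or len(states) != len(occupancies):
        raise ValueError("need one occupancy per state")
    occ = np.asarray(occupancies, dtype=float)
    if np.any(occ < 0):
        raise ValueError("occupancies must be non-negative")
    if abs(occ.sum() - 1.0) > tol:
        raise ValueError(f"occupancies must sum to 1, got {occ.sum()!r}")
    grid = states[0].grid
    for s in states[1:]:
        if s.grid.shape != grid.shape or not np.array_equal(s.grid, grid):
            raise ValueError("all states must share one wavelength grid")
    values = np.zeros_like(grid, dtype=float)
    for f, s in zip(occ, states):
        values += f * _gaussian_sum(s.bands, grid)
    return Spectrum(grid, values)


def difference_spectrum(dark: Spectrum, irradiated: Spectrum) -> Spectrum:
    """Difference spectrum, dark-adapted minus irradiated (fixed sign).

    Its maximum sits near the Pr band and its far-red minimum locates the
    Pfr absorption maximum.
    """
    if dark.grid.shape != irradiated.grid.shape or not np.array_equal(
        dark.grid, irradiated.grid
    ):
        raise ValueError("difference spectrum requires identical grids")
    return Spectrum(dark.grid, dark.values - irradiated.values)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i-1, i, i+1 (general spacing)."""
    xs = x[i - 1 : i + 2]
    ys = y[i - 1 : i + 2]
    a, b, _ = np.polyfit(xs - xs[1], ys, 2)
    if a == 0.0:
        return float(x[i])
    v = -b / (2.0 * a) + xs[1]
    # keep the refined position inside the bracketing interval
    if not (xs[0] <= v <= xs[2]):
        return float(x[i])
    return float(v)


def find_extrema(
    spec: Spectrum, *, refine: bool = True
) -> tuple[list[float], list[float]]:
    """Interior local maxima and minima of a sampled spectrum.

    Extrema are located by strict three-point comparison; with
    ``refine=True`` each is sharpened by parabolic interpolation through
    its three bracketing samples, which recovers nm-scale peak positions
    from a coarse (e.g. 10-nm) measurement grid.  A flat spectrum has no
    interior extrema.
    """
    x, y = spec.grid, spec.values
    if x.size < 3:
        raise ValueError("need at least 3 grid points to locate extrema")
    maxima: list[float] = []
    minima: list[float] = []
    for i in range(1, x.size - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            maxima.append(_parabolic_refine(x, y, i) if refine else float(x[i]))
        elif y[i] < y[i - 1] and y[i] < y[i + 1]:
            minima.append(_parabolic_refine(x, y, i) if refine else float(x[i]))
    return maxima, minima


@dataclass(frozen=True)
class IsosbesticResult:
    """Crossing wavelengths of two spectra.

    ``degenerate`` is True when the two spectra coincide everywhere, in
    which case *every* wavelength is a crossing and ``wavelengths`` is
    left empty rather than unbounded.
    """

    wavelengths: tuple[float, ...] = field(default_factory=tuple)
    degenerate: bool = False

    def __iter__(self):
        return iter(self.wavelengths)

    def __len__(self) -> int:
        return len(self.wavelengths)


def isosbestic_points(
    a: Spectrum, b: Spectrum, *, degenerate_tol: float = 1e-12
) -> IsosbesticResult:
    """Wavelengths where two spectra cross (sign changes of a − b).

    Crossings between grid points are located by linear interpolation.
    At an isosbestic wavelength every Beer–Lambert mixture of the two
    underlying species has the same absorbance, which is the experimental
    signature of clean two-state interconversion.
    """
    if a.grid.shape != b.grid.shape or not np.array_equal(a.grid, b.grid):
        raise ValueError("isosbestic detection requires identical grids")
    d = a.values - b.values
    if np.all(np.abs(d) <= degenerate_tol):
        return IsosbesticResult(degenerate=True)
    x = a.grid
    crossings: list[float] = []
    for i in range(x.size - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            crossings.append(float(x[i]))
        elif d0 * d1 < 0:
            # linear interpolation between the bracketing samples
            crossings.append(float(x[i] + (x[i + 1] - x[i]) * d0 / (d0 - d1)))
    if d[-1] == 0.0:
        crossings.append(float(x[-1]))
    return IsosbesticResult(tuple(crossings))
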