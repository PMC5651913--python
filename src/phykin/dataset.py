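"""Time-resolved multi-wavelength absorbance data container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeResolvedDataset:
    """Absorbance matrix over time (minutes) and wavelength (nm).

    ``absorbance[i, j]`` is the absorbance at ``times[i]`` and
    ``wavelengths[j]``.  ``meta`` carries acquisition metadata such as the
    fluence rate, temperature, scheme and RNG seed.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or w.ndim != 1:
            raise ValueError("times and wavelengths must be 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if a.shape != (t.size, w.size):
            raise ValueError(
                f"absorbance shape {a.shape} does not match "
                f"(n_times={t.size}, n_wavelengths={w.size})"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "meta", dict(self.meta))

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def column(self, wavelength: float) -> np.ndarray:
        """Absorbance trace at one wavelength."""
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength} nm not in dataset")
        return self.absorbance[:, idx[0]]

    def subset(self, wavelengths) -> "TimeResolvedDataset":
        """Restrict to the given wavelengths (order preserved)."""
        cols = []
        for w in wavelengths:
            idx = np.nonzero(np.isclose(self.wavelengths, w))[0]
            if idx.size == 0:
                raise KeyError(f"wavelength {w} nm not in dataset")
            cols.append(idx[0])
        return TimeResolvedDataset(
            self.times,
            self.wavelengths[cols],
            self.absorbance[:, cols],
            self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """As a DataFrame with a ``time_min`` column and wavelength columns."""
        df = pd.DataFrame(
            self.absorbance,
            columns=[_fmt_wavelength(w) for w in self.wavelengths],
        )
        df.insert(0, "time_min", self.times)
        return df


def _fmt_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else str(float(w))
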