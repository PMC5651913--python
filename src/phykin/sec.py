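"""Size-exclusion chromatography (SEC) quantitation and dimerization model.

SEC reports an apparent molecular mass through the partition coefficient
K_AV = (Ve − V0)/(Vt − V0), calibrated against size standards via the
usual log-linear relation log10(M) = slope·K_AV + intercept.

Concentration-dependent apparent mass is interpreted with a mass-action
monomer–dimer equilibrium, 2·Mono ⇌ Di with Kd = [Mono]²/[Di]: the
weight-average mass rises smoothly from the monomer mass M at infinite
dilution to 2M in the tight-binding/high-concentration limit.  This is
the behaviour shown by photosensory-module fragments that keep one
dimerization interface but lose the C-terminal one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "SECRun",
    "Calibration",
    "MonomerDimerModel",
    "KdFitResult",
    "SECRangeWarning",
    "kav",
    "calibrate",
    "apparent_mass",
    "monomer_dimer_mass",
    "fit_kd",
    "mg_ml_to_molar",
]


class SECRangeWarning(UserWarning):
    """Analyte eluting outside the [V0, Vt] partition range."""


@dataclass(frozen=True)
class SECRun:
    """One SEC elution: elution, void and total volumes (mL)."""

    Ve: float
    V0: float
    Vt: float
    sample_conc: float | None = None  # mg/mL

    def __post_init__(self) -> None:
        if not self.V0 < self.Vt:
            raise ValueError("void volume must be smaller than total volume")


@dataclass(frozen=True)
class Calibration:
    """Log-linear SEC calibration: log10(mass/kDa) = slope·K_AV + intercept."""

    slope: float
    intercept: float
    standards: tuple[tuple[float, float], ...]  # (mass_kda, kav)
    r_squared: float


@dataclass(frozen=True)
class MonomerDimerModel:
    """Mass-action monomer–dimer equilibrium of a protein of mass M (kDa).

    Kd is the dissociation constant of the dimer in molar units,
    Kd = [Mono]²/[Di].  mg/mL ↔ molar conversion uses the monomer mass.
    """

    M: float
    Kd: float

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError("monomer mass must be positive")
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")


@dataclass(frozen=True)
class KdFitResult:
    """Fitted dimer Kd with an identifiability flag.

    ``flag`` is None for a regular fit, "unidentifiable-high" when the
    series is flat at the monomer mass (only a lower bound on Kd exists),
    and "unidentifiable-low" when flat at the dimer mass.
    """

    kd: float | None
    rss: float | None
    flag: str | None = None


def kav(run: SECRun) -> float:
    """Partition coefficient K_AV = (Ve − V0)/(Vt − V0).

    Values outside [0, 1] (analyte excluded from, or retained beyond, the
    column's fractionation range) are returned as computed with a
    :class:`SECRangeWarning`.
    """
    value = (run.Ve - run.V0) / (run.Vt - run.V0)
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"elution volume {run.Ve} mL outside [V0={run.V0}, Vt={run.Vt}]: "
            "analyte outside the column partition range",
            SECRangeWarning,
            stacklevel=2,
        )
    return value


def calibrate(standards: Sequence[tuple[float, float]]) -> Calibration:
    """Ordinary least-squares SEC calibration from (mass_kda, K_AV) standards."""
    pts = [(float(m), float(k)) for m, k in standards]
    if len({k for _, k in pts}) < 2:
        raise ValueError("need at least 2 standards with distinct K_AV")
    x = np.array([k for _, k in pts])
    y = np.log10([m for m, _ in pts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope >= 0:
        warnings.warn(
            "calibration slope is non-negative; larger masses should elute "
            "earlier (smaller K_AV)",
            UserWarning,
            stacklevel=2,
        )
    return Calibration(float(slope), float(intercept), tuple(pts), r2)


def apparent_mass(cal: Calibration, kav_value: float) -> float:
    """Apparent molecular mass (kDa) from the calibration line."""
    return float(10.0 ** (cal.slope * kav_value + cal.intercept))


def mg_ml_to_molar(conc_mg_ml: float, mass_kda: float) -> float:
    """Convert mg/mL to molar using the given molecular mass."""
    return conc_mg_ml / (mass_kda * 1000.0)


def _species_concentrations(model: MonomerDimerModel, C: float) -> tuple[float, float]:
    """Equilibrium [Mono], [Di] (molar) at total monomer-equivalent C (molar).

    Conservation C = [Mono] + 2[Di] with Kd = [Mono]²/[Di] gives the
    quadratic 2[Mono]² + Kd[Mono] − Kd·C = 0, hence
    [Mono] = (−Kd + sqrt(Kd² + 8·Kd·C))/4.
    """
    kd = model.Kd
    mono = (-kd + math.sqrt(kd * kd + 8.0 * kd * C)) / 4.0
    di = mono * mono / kd
    return mono, di


def monomer_dimer_mass(
    model: MonomerDimerModel, total_conc: float
) -> tuple[float, float]:
    """Weight-average mass (kDa) and dimer mass fraction at a total
    chromoprotein concentration in mg/mL.

    Returns ``(M_w, f_dimer)`` where
    M_w = M·([Mono] + 4[Di])/([Mono] + 2[Di]) and f_dimer = 2[Di]/C is the
    fraction of protein mass in the dimer.  The dilution limit C → 0
    gives (M, 0); the tight-binding limit gives (2M, 1).
    """
    if total_conc < 0:
        raise ValueError("concentration must be >= 0")
    if total_conc == 0:
        return model.M, 0.0
    C = mg_ml_to_molar(total_conc, model.M)
    mono, di = _species_concentrations(model, C)
    mw = model.M * (mono + 4.0 * di) / (mono + 2.0 * di)
    f_dimer = 2.0 * di / C
    return float(mw), float(f_dimer)


def fit_kd(
    series: Sequence[tuple[float, float]],
    M: float,
    *,
    log10_kd_bounds: tuple[float, float] = (-15.0, 3.0),
    flat_rtol: float = 1e-9,
) -> KdFitResult:
    """Least-squares dimer Kd from an SEC (concentration, observed-mass) series.

    The search runs over log10(Kd) within ``log10_kd_bounds``; the monomer
    mass M (kDa) is held fixed.  Requires at least 3 concentrations
    spanning at least a factor of 10.  A series flat at M or at 2M carries
    no Kd information and is returned flagged instead of fitted.
    """
    pts = [(float(c), float(m)) for c, m in series]
    if len(pts) < 3:
        raise ValueError("need at least 3 concentrations")
    concs = np.array([c for c, _ in pts])
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    if concs.max() / concs.min() < 10.0:
        raise ValueError("concentration series must span at least 10-fold")
    obs = np.array([m for _, m in pts])

    if np.allclose(obs, M, rtol=flat_rtol, atol=0):
        return KdFitResult(kd=None, rss=None, flag="unidentifiable-high")
    if np.allclose(obs, 2.0 * M, rtol=flat_rtol, atol=0):
        return KdFitResult(kd=None, rss=None, flag="unidentifiable-low")

    def rss_of(log10_kd: float) -> float:
        model = MonomerDimerModel(M=M, Kd=10.0**log10_kd)
        pred = np.array([monomer_dimer_mass(model, c)[0] for c in concs])
        return float(np.sum((obs - pred) ** 2))

    res = minimize_scalar(
        rss_of, bounds=log10_kd_bounds, method="bounded",
        options={"xatol": 1e-12},
    )
    return KdFitResult(kd=float(10.0**res.x), rss=float(res.fun), flag=None)
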