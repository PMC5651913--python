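"""First-order kinetic schemes for phytochrome photoconversion and reversion.

The photoreceptor is modelled as a continuous-time linear kinetic network
over the photostates Pr, Pfr and (optionally) a lumped Bleached
photoproduct.  Photochemical rates scale linearly with the fluence rate of
the actinic light (low-intensity photochemistry), thermal reversion
Pfr → Pr proceeds in darkness, and the Bleached state is reachable from Pr
under red light and decays thermally back to Pr.

Canonical units throughout: time in minutes, rate constants in min⁻¹,
fluence rate in μmol·m⁻²·s⁻¹; photoconversion coefficients are therefore
min⁻¹ per μmol·m⁻²·s⁻¹.

A separate sequential "dimer chain" models cooperative thermal reversion
of the Pfr/Pfr homodimer: once one subunit has reverted, the remaining Pfr
reverts at a different (typically slower, HKRD-stabilized) rate, producing
biexponential bulk Pfr decay:

    PfrPfr --k_fast--> PfrPr --k_slow--> PrPr
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

from .dataset import TimeResolvedDataset
from .spectra import StateSpectrum, _gaussian_sum

__all__ = [
    "PhotoSystem",
    "DimerChain",
    "OccupancyTrace",
    "DimerReversionResult",
    "rate_matrix",
    "simulate",
    "photostationary_fraction",
    "dimer_reversion_trace",
    "absorbance_timecourse",
]

_ALLOWED_STATES = ("Pr", "Pfr", "Bleached")


@dataclass(frozen=True)
class PhotoSystem:
    """A phytochrome kinetic scheme.

    Parameters
    ----------
    states : tuple of str
        Ordered subset of {"Pr", "Pfr", "Bleached"}.
    sigma_fwd, sigma_rev : float
        Photoconversion coefficients Pr→Pfr and Pfr→Pr, in min⁻¹ per
        μmol·m⁻²·s⁻¹ of actinic fluence rate.
    k_therm : float
        Thermal (dark) reversion constant Pfr→Pr in min⁻¹.
    sigma_bleach : float
        Photochemical Pr→Bleached coefficient (same units as sigma_fwd).
    k_bleach_decay : float
        Thermal Bleached→Pr decay constant in min⁻¹.
    """

    states: tuple[str, ...] = ("Pr", "Pfr")
    sigma_fwd: float = 0.0
    sigma_rev: float = 0.0
    k_therm: float = 0.0
    sigma_bleach: float = 0.0
    k_bleach_decay: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(set(self.states)) != len(self.states):
            raise ValueError("states must be unique")
        for s in self.states:
            if s not in _ALLOWED_STATES:
                raise ValueError(f"unknown state {s!r}")
        for name in ("sigma_fwd", "sigma_rev", "k_therm", "sigma_bleach", "k_bleach_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if "Bleached" in self.states and "Pr" not in self.states:
            raise ValueError("Bleached state requires Pr in the scheme")

    def index(self, state: str) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class DimerChain:
    """Cooperative-dimer thermal-reversion chain PfrPfr → PfrPr → PrPr."""

    k_fast: float
    k_slow: float

    def __post_init__(self) -> None:
        if not (self.k_fast > 0 and self.k_slow > 0):
            raise ValueError("dimer-chain rate constants must be positive")


@dataclass(frozen=True)
class OccupancyTrace:
    """Per-state occupancy fractions over time (rows sum to 1)."""

    times: np.ndarray
    occupancies: np.ndarray  # shape (n_times, n_states)
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        occ = np.asarray(self.occupancies, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "occupancies", occ)
        object.__setattr__(self, "states", tuple(self.states))
        if occ.shape != (t.size, len(self.states)):
            raise ValueError("occupancy matrix shape mismatch")

    def state(self, label: str) -> np.ndarray:
        return self.occupancies[:, self.states.index(label)]


def rate_matrix(sys: PhotoSystem, fluence: float) -> np.ndarray:
    """Generator matrix Q (min⁻¹) of the scheme at the given fluence rate.

    Column convention: Q[j, i] is the rate from state i to state j, and
    each column sums to zero, so d/dt p = Q p conserves total occupancy.
    """
    if fluence < 0:
        raise ValueError("fluence rate must be >= 0")
    n = len(sys.states)
    Q = np.zeros((n, n))

    def add(frm: str, to: str, rate: float) -> None:
        if rate == 0.0 or frm not in sys.states or to not in sys.states:
            return
        i, j = sys.index(frm), sys.index(to)
        Q[j, i] += rate
        Q[i, i] -= rate

    add("Pr", "Pfr", sys.sigma_fwd * fluence)
    add("Pfr", "Pr", sys.sigma_rev * fluence + sys.k_therm)
    add("Pr", "Bleached", sys.sigma_bleach * fluence)
    add("Bleached", "Pr", sys.k_bleach_decay)
    return Q


def simulate(
    sys: PhotoSystem,
    fluence: float,
    init: Sequence[float],
    times: Sequence[float],
    *,
    init_tol: float = 1e-8,
) -> OccupancyTrace:
    """Exact occupancies p(t) = expm(Q·t)·p(0) at the requested times.

    The propagator is evaluated by eigendecomposition of the (small)
    generator, falling back to per-time matrix exponentials if the
    generator is defective; no fixed-step integration is involved.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    p0 = np.asarray(init, dtype=float)
    if p0.shape != (len(sys.states),):
        raise ValueError("init must have one entry per state")
    if np.any(p0 < -init_tol) or abs(p0.sum() - 1.0) > init_tol:
        raise ValueError("init must be a probability vector summing to 1")

    Q = rate_matrix(sys, fluence)
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError("near-defective eigenbasis")
        c = Vinv @ p0
        # p(t) = V diag(e^{λt}) V⁻¹ p0, evaluated for all times at once
        occ = np.real(np.einsum("ij,tj,j->ti", V, np.exp(np.outer(t, lam)), c))
    except np.linalg.LinAlgError:
        occ = np.stack([expm(Q * ti) @ p0 for ti in t])
    occ[t == 0.0] = p0  # the propagator at t=0 is the identity
    # clip eigen-roundoff; renormalize to preserve the row-sum invariant
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return OccupancyTrace(t, occ, sys.states)


def photostationary_fraction(sys: PhotoSystem, fluence: float) -> float:
    """Steady-state Pfr fraction under continuous irradiation.

    For the two-state scheme this is σ_f·I / (σ_f·I + σ_r·I + k_therm);
    in general it is the Pfr component of the generator's (unique)
    stationary null vector.
    """
    Q = rate_matrix(sys, fluence)
    if not np.any(Q):
        raise ValueError("all rates are zero: no unique steady state")
    ns = null_space(Q)
    if ns.shape[1] != 1:
        raise ValueError("steady state is not unique for this scheme")
    p = ns[:, 0]
    p = p / p.sum()
    if "Pfr" not in sys.states:
        return 0.0
    return float(p[sys.index("Pfr")])


@dataclass(frozen=True)
class DimerReversionResult:
    """Bulk Pfr-fraction decay of the cooperative dimer chain.

    ``pfr_fraction[i]`` is f(times[i]) = [2·PfrPfr(t) + PfrPr(t)] / 2
    starting from pure PfrPfr.  For k_fast ≠ k_slow the exact closed form
    is f(t) = amp_fast·exp(−k_fast·t) + amp_slow·exp(−k_slow·t); in the
    degenerate limit k_fast = k_slow = k it is (1 + k·t/2)·exp(−k·t) and
    the biexponential amplitudes are undefined (reported as NaN).
    """

    times: np.ndarray
    pfr_fraction: np.ndarray
    k_fast: float
    k_slow: float
    amp_fast: float
    amp_slow: float
    degenerate: bool = False
    occupancies: OccupancyTrace | None = field(default=None, repr=False)


def dimer_reversion_trace(
    chain: DimerChain,
    times: Sequence[float],
    *,
    degeneracy_rtol: float = 1e-6,
) -> DimerReversionResult:
    """Solve PfrPfr →(k_fast) PfrPr →(k_slow) PrPr from pure PfrPfr.

    Returns the total Pfr fraction trace together with its exact
    biexponential decomposition.  The amplitude split depends only on the
    k_fast/k_slow ratio:

        amp_fast = (k_fast − 2·k_slow) / (2·(k_fast − k_slow))
        amp_slow = k_fast / (2·(k_fast − k_slow))

    Near-equal rates (|k_fast − k_slow| < degeneracy_rtol·k_fast) switch
    to the analytic t·exp limit to avoid catastrophic cancellation.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    kf, ks = chain.k_fast, chain.k_slow

    if abs(kf - ks) < degeneracy_rtol * kf:
        k = 0.5 * (kf + ks)
        pp = np.exp(-k * t)  # PfrPfr
        pm = k * t * np.exp(-k * t)  # PfrPr
        f = (2.0 * pp + pm) / 2.0
        amp_fast = amp_slow = float("nan")
        degenerate = True
    else:
        pp = np.exp(-kf * t)
        pm = kf / (kf - ks) * (np.exp(-ks * t) - np.exp(-kf * t))
        amp_slow = kf / (2.0 * (kf - ks))
        amp_fast = 1.0 - amp_slow
        f = amp_fast * np.exp(-kf * t) + amp_slow * np.exp(-ks * t)
        degenerate = False

    occ = OccupancyTrace(
        t,
        np.stack([pp, pm, 1.0 - pp - pm], axis=1),
        ("PfrPfr", "PfrPr", "PrPr"),
    )
    return DimerReversionResult(
        times=t,
        pfr_fraction=f,
        k_fast=kf,
        k_slow=ks,
        amp_fast=float(amp_fast),
        amp_slow=float(amp_slow),
        degenerate=degenerate,
        occupancies=occ,
    )


def absorbance_timecourse(
    trace: OccupancyTrace,
    basis: Sequence[StateSpectrum],
    wavelengths: Sequence[float],
) -> TimeResolvedDataset:
    """Render an occupancy trace into absorbance, A(t, λ) = Σ_s p_s(t)·ε_s(λ).

    ``basis`` must contain one StateSpectrum per state of the trace
    (matched by label).  Wavelengths are evaluated directly from the band
    model and need not lie on the basis grids.
    """
    by_label = {s.state_label: s for s in basis}
    missing = [s for s in trace.states if s not in by_label]
    if missing:
        raise ValueError(f"missing state spectra for {missing}")
    w = np.asarray(wavelengths, dtype=float)
    eps = np.stack(
        [_gaussian_sum(by_label[s].bands, w) for s in trace.states]
    )  # (n_states, n_wavelengths)
    A = trace.occupancies @ eps
    return TimeResolvedDataset(trace.times, w, A)
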