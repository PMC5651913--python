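"""CSV and YAML I/O.

File conventions:

* Time-resolved dataset CSV: optional ``# key=value`` provenance header
  lines, then a header row ``time_min,<λ1>,<λ2>,...`` with wavelength
  column names in integer nm.  UTF-8, '.' decimal separator.
* Spectrum CSV: two columns ``wavelength_nm,absorbance``.
* SEC runs CSV: ``sample,conc_mg_ml,Ve_ml,V0_ml,Vt_ml``.
* SEC standards CSV: ``mass_kda,kav``.
* Scheme config: YAML describing a kinetic scheme and acquisition
  (see :func:`load_generator_config`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dataset import TimeResolvedDataset
from .kinetics import DimerChain, PhotoSystem
from .sec import SECRun
from .spectra import Spectrum
from .synthetic import (
    BiexponentialScheme,
    GeneratorConfig,
    default_state_spectra,
    get_entry,
    load_table1,
    replay_config,
)

__all__ = [
    "write_timecourse_csv",
    "read_timecourse_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_sec_runs_csv",
    "read_standards_csv",
    "load_generator_config",
]


def _coerce(text: str) -> Any:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text == "None":
        return None
    return text


def write_timecourse_csv(ds: TimeResolvedDataset, path: str | Path) -> None:
    """Write a dataset with ``# key=value`` provenance header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for key, value in ds.meta.items():
            fh.write(f"# {key}={value}\n")
        ds.to_frame().to_csv(fh, index=False)


def read_timecourse_csv(path: str | Path) -> TimeResolvedDataset:
    """Read a dataset CSV written by :func:`write_timecourse_csv`."""
    path = Path(path)
    meta: dict[str, Any] = {}
    body_lines = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
            else:
                body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    if df.columns[0] != "time_min" or df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(
            f"{path}: expected a 'time_min' column followed by wavelength columns"
        )
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: wavelength column names must be numeric") from exc
    return TimeResolvedDataset(
        df["time_min"].to_numpy(float), wavelengths,
        df.iloc[:, 1:].to_numpy(float), meta,
    )


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.grid, "absorbance": spec.values}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["wavelength_nm", "absorbance"]:
        raise ValueError(f"{path}: expected columns wavelength_nm,absorbance")
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["absorbance"].to_numpy(float))


def read_sec_runs_csv(path: str | Path) -> list[tuple[str, SECRun]]:
    """Read SEC elutions: sample,conc_mg_ml,Ve_ml,V0_ml,Vt_ml."""
    df = pd.read_csv(path)
    required = ["sample", "conc_mg_ml", "Ve_ml", "V0_ml", "Vt_ml"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"{path}: expected columns {','.join(required)}")
    return [
        (
            str(row["sample"]),
            SECRun(
                Ve=float(row["Ve_ml"]), V0=float(row["V0_ml"]),
                Vt=float(row["Vt_ml"]), sample_conc=float(row["conc_mg_ml"]),
            ),
        )
        for _, row in df.iterrows()
    ]


def read_standards_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read SEC size standards: mass_kda,kav."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["mass_kda", "kav"]:
        raise ValueError(f"{path}: expected columns mass_kda,kav")
    return [(float(m), float(k)) for m, k in zip(df["mass_kda"], df["kav"])]


def _parse_times(raw: Any) -> np.ndarray:
    if isinstance(raw, dict):
        return np.linspace(
            float(raw["start"]), float(raw["stop"]), int(raw["num"])
        )
    return np.asarray([float(x) for x in raw], dtype=float)


def load_generator_config(
    path: str | Path, *, seed: int | None = None
) -> GeneratorConfig:
    """Build a :class:`~phykin.synthetic.GeneratorConfig` from a YAML file.

    The scheme is given by exactly one of:

    * mechanistic keys ``states``, ``sigma_fwd``, ``sigma_rev``,
      ``k_therm_per_min`` (+ optional ``sigma_bleach``,
      ``k_bleach_decay_per_min``), solved exactly;
    * ``dimer_chain: {k_fast, k_slow}`` — cooperative reversion from
      pure PfrPfr;
    * ``biexponential: {rates, amplitudes, direction, plateau}``;
    * ``replay: {construct, bilin, measurement}`` — bundled published
      constants.

    Common keys: ``fluence_umol_m2_s``, ``times_min`` (list or
    ``{start, stop, num}``), ``wavelengths_nm``, ``noise_sd``, ``seed``,
    ``basis: {pr_max_nm, pfr_max_nm}``, ``init``.  A ``seed`` argument
    overrides the file's seed.
    """
    raw = yaml.safe_load(Path(path).read_text("utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    seed = seed if seed is not None else raw.get("seed")
    noise_sd = float(raw.get("noise_sd", 0.0))

    if "replay" in raw:
        rep = raw["replay"]
        entry = get_entry(load_table1(), rep["construct"], rep["bilin"])
        times = _parse_times(raw["times_min"]) if "times_min" in raw else None
        return replay_config(
            entry,
            rep.get("measurement", "thermal_reversion"),
            noise_sd=noise_sd, seed=seed, times=times,
        )

    if "times_min" not in raw:
        raise ValueError(f"{path}: times_min is required")
    times = _parse_times(raw["times_min"])

    scheme: PhotoSystem | DimerChain | BiexponentialScheme
    if "dimer_chain" in raw:
        dc = raw["dimer_chain"]
        scheme = DimerChain(k_fast=float(dc["k_fast"]), k_slow=float(dc["k_slow"]))
    elif "biexponential" in raw:
        bx = raw["biexponential"]
        scheme = BiexponentialScheme(
            rates=tuple(float(k) for k in bx["rates"]),
            amplitudes=(
                tuple(float(a) for a in bx["amplitudes"])
                if bx.get("amplitudes") is not None else None
            ),
            direction=bx.get("direction", "decay"),
            plateau=float(bx.get("plateau", 1.0)),
        )
    elif "states" in raw:
        scheme = PhotoSystem(
            states=tuple(raw["states"]),
            sigma_fwd=float(raw.get("sigma_fwd", 0.0)),
            sigma_rev=float(raw.get("sigma_rev", 0.0)),
            k_therm=float(raw.get("k_therm_per_min", 0.0)),
            sigma_bleach=float(raw.get("sigma_bleach", 0.0)),
            k_bleach_decay=float(raw.get("k_bleach_decay_per_min", 0.0)),
        )
    else:
        raise ValueError(
            f"{path}: config must define 'states', 'dimer_chain', "
            "'biexponential' or 'replay'"
        )

    basis = None
    if "basis" in raw:
        b = raw["basis"]
        basis = default_state_spectra(
            float(b.get("pr_max_nm", 664.0)), float(b.get("pfr_max_nm", 724.0))
        )
    kwargs: dict[str, Any] = {}
    if "wavelengths_nm" in raw:
        kwargs["wavelengths"] = np.asarray(
            [float(w) for w in raw["wavelengths_nm"]], dtype=float
        )
    if "init" in raw:
        kwargs["init"] = tuple(float(x) for x in raw["init"])
    return GeneratorConfig(
        scheme=scheme,
        times=times,
        basis=basis,
        fluence=float(raw.get("fluence_umol_m2_s", 0.0)),
        noise_sd=noise_sd,
        seed=seed,
        label=str(raw.get("label", "")),
        **kwargs,
    )
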