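"""CSV I/O for decay traces, emission spectra and titrations.

Column conventions:

* decay trace: ``time_ms,counts``
* emission spectrum: ``wavelength_nm,intensity,quencher_conc_M,dilution_factor``
  (concentration and dilution constant within one file)
* titration: ``quencher_conc_M,F,F0``
"""

from __future__ import annotations

import pandas as pd

from .lret import DecayTrace
from .quenching import EmissionSpectrum, QuenchTitration


def write_decay_csv(trace: DecayTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.times, "counts": trace.counts}).to_csv(
        path, index=False
    )


def read_decay_csv(path) -> DecayTrace:
    df = pd.read_csv(path)
    missing = {"time_ms", "counts"} - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV missing columns: {sorted(missing)}")
    return DecayTrace(times=df["time_ms"].to_numpy(), counts=df["counts"].to_numpy())


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "intensity": spectrum.intensities,
            "quencher_conc_M": spectrum.quencher_conc,
            "dilution_factor": spectrum.dilution_factor,
        }
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> EmissionSpectrum:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "intensity", "quencher_conc_M", "dilution_factor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV missing columns: {sorted(missing)}")
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        quencher_conc=float(df["quencher_conc_M"].iloc[0]),
        dilution_factor=float(df["dilution_factor"].iloc[0]),
    )


def write_titration_csv(titration: QuenchTitration, path) -> None:
    pd.DataFrame(
        {
            "quencher_conc_M": titration.concentrations,
            "F": titration.F,
            "F0": titration.F0,
        }
    ).to_csv(path, index=False)


def read_titration_csv(path) -> QuenchTitration:
    df = pd.read_csv(path)
    missing = {"quencher_conc_M", "F"} - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    f0 = float(df["F0"].iloc[0]) if "F0" in df.columns else float(df["F"].iloc[0])
    return QuenchTitration(
        concentrations=df["quencher_conc_M"].to_numpy(),
        F=df["F"].to_numpy(),
        F0=f0,
    )
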