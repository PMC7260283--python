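"""Iodide-quenching accessibility analysis (Stern–Volmer).

Emission spectra of TMR-labeled single-cysteine constructs are titrated
with KI; collisional quenching by iodide lowers the fluorescence of
water-exposed fluorophores.  Intensities read at the emission maximum
(572 nm for TMR) are corrected for sample dilution and normalized to the
quencher-free intensity, and the linear Stern–Volmer relation

    F0 / F = 1 + K_SV * [Q]

is fitted by ordinary least squares.  K_SV (M^-1) is a proxy for solvent
accessibility of the labeling site; sites whose slopes agree within
statistical error are called overlapping, i.e. equally accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EmissionSpectrum:
    """A single emission scan at one quencher concentration."""

    wavelengths: np.ndarray  # nm, ascending
    intensities: np.ndarray  # arbitrary fluorescence units
    quencher_conc: float  # M
    dilution_factor: float = 1.0  # >= 1, cumulative

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must be equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be ascending")
        if self.quencher_conc < 0:
            raise ValueError("quencher concentration must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class QuenchTitration:
    """Dilution-corrected intensities F versus quencher concentration."""

    concentrations: np.ndarray  # M, ascending, first entry 0
    F: np.ndarray  # corrected intensities
    F0: float  # intensity at zero quencher

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.concentrations.shape != self.F.shape:
            raise ValueError("concentrations and F must be equal length")
        if self.concentrations[0] != 0:
            raise ValueError("titration must start at zero quencher")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be ascending")
        if np.any(self.F <= 0) or self.F0 <= 0:
            raise ValueError("intensities must be positive")


@dataclass
class SternVolmerFit:
    KSV: float  # M^-1
    intercept: float  # expected ~ 1
    r_squared: float
    KSV_se: float
    intercept_se: float = float("nan")


def extract_intensity(spectra, wavelength: float) -> QuenchTitration:
    """Build a titration from spectra by reading one emission wavelength.

    F at each concentration is the intensity at the nearest recorded
    wavelength multiplied by that spectrum's dilution factor (spectra are
    recorded on a 1 nm grid, so nearest-neighbour lookup suffices);
    F0 comes from the zero-quencher spectrum.  Output is sorted by
    concentration.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    concs, values = [], []
    for spec in spectra:
        if not spec.wavelengths[0] <= wavelength <= spec.wavelengths[-1]:
            raise ValueError(
                f"wavelength {wavelength} nm outside recorded range "
                f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
            )
        idx = int(np.argmin(np.abs(spec.wavelengths - wavelength)))
        concs.append(spec.quencher_conc)
        values.append(spec.intensities[idx] * spec.dilution_factor)
    concs = np.asarray(concs)
    values = np.asarray(values)
    if not np.any(concs == 0):
        raise ValueError("no zero-quencher spectrum present")
    order = np.argsort(concs, kind="stable")
    concs, values = concs[order], values[order]
    return QuenchTitration(concentrations=concs, F=values, F0=float(values[0]))


def fit_stern_volmer(titration: QuenchTitration) -> SternVolmerFit:
    """Ordinary least squares of F0/F against [Q]; slope is K_SV.

    The intercept is left free (its expected value is 1) so that a
    deviation from 1 remains visible as a diagnostic.
    """
    q = titration.concentrations
    if np.unique(q).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    y = titration.F0 / titration.F
    res = stats.linregress(q, y)
    return SternVolmerFit(
        KSV=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        KSV_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def compare_accessibility(fits: dict[str, SternVolmerFit]) -> pd.DataFrame:
    """Compare K_SV across labeling sites.

    Returns a table with one row per site (K_SV ± se) plus pairwise
    slope-difference z-scores, z = (K1 - K2)/sqrt(se1^2 + se2^2).  The
    frame's ``attrs['overlapping']`` is True when every pairwise |z| < 2,
    the working criterion for "equally accessible"; ``attrs['pairwise']``
    holds the per-pair z-scores.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 sites to compare")
    names = list(fits)
    table = pd.DataFrame(
        {
            "site": names,
            "KSV": [fits[n].KSV for n in names],
            "KSV_se": [fits[n].KSV_se for n in names],
            "intercept": [fits[n].intercept for n in names],
            "r_squared": [fits[n].r_squared for n in names],
        }
    ).set_index("site")
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pooled = np.hypot(fits[a].KSV_se, fits[b].KSV_se)
            diff = fits[a].KSV - fits[b].KSV
            pairwise[(a, b)] = float(diff / pooled) if pooled > 0 else (
                0.0 if diff == 0 else float("inf")
            )
    table.attrs["pairwise"] = pairwise
    table.attrs["overlapping"] = all(abs(z) < 2 for z in pairwise.values())
    return table
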