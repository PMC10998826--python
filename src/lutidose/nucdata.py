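"""Physical constants and Lu-177 decay data.

Decay data (half-life, electron and photon emission tables), electron CSDA
ranges in water, and photon attenuation coefficients ship as versioned JSON
files under ``lutidose/data``.  Energies are stored in keV and times in
seconds throughout this module; the single conversion constant to joules
(:data:`KEV_TO_J`) lives here so every downstream dose is traceable to it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "KEV_TO_J",
    "DecayData",
    "load_decay_data",
    "physical_decay_constant",
    "mean_electron_energy",
    "mean_photon_energy",
    "CsdaTable",
    "load_csda_table",
    "PhotonAttenuation",
    "load_photon_attenuation",
]

#: Exact conversion, 1 keV in joules (SI 2019 elementary charge).
KEV_TO_J = 1.602176634e-16


def _data_text(name: str) -> str:
    return resources.files("lutidose.data").joinpath(name).read_text()


@dataclass(frozen=True)
class DecayData:
    """Emission table of a radionuclide.

    Parameters
    ----------
    half_life_s:
        Physical half-life in seconds.
    electron_energies_keV, electron_yields:
        Electron emissions per decay — binned beta spectrum plus discrete
        conversion/Auger lines.  Yields are emissions per decay.
    photon_energies_keV, photon_yields:
        Photon lines (gammas and X-rays) per decay.
    """

    half_life_s: float
    electron_energies_keV: np.ndarray
    electron_yields: np.ndarray
    photon_energies_keV: np.ndarray
    photon_yields: np.ndarray
    nuclide: str = "Lu-177"
    version: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("physical half-life must be positive")
        for arr, what in (
            (self.electron_energies_keV, "electron energies"),
            (self.photon_energies_keV, "photon energies"),
        ):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError(f"{what} must be strictly positive")
        for arr, what in (
            (self.electron_yields, "electron yields"),
            (self.photon_yields, "photon yields"),
        ):
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{what} must be non-negative")


def load_decay_data(nuclide: str = "lu177") -> DecayData:
    """Load the packaged decay data file for *nuclide* (only Lu-177 ships)."""
    raw = json.loads(_data_text(f"{nuclide}_decay.json"))
    return DecayData(
        half_life_s=float(raw["half_life_s"]),
        electron_energies_keV=np.array([l["E_keV"] for l in raw["electrons"]]),
        electron_yields=np.array([l["yield"] for l in raw["electrons"]]),
        photon_energies_keV=np.array([l["E_keV"] for l in raw["photons"]]),
        photon_yields=np.array([l["yield"] for l in raw["photons"]]),
        nuclide=raw.get("nuclide", nuclide),
        version=raw.get("version", ""),
    )


def physical_decay_constant(d: DecayData) -> float:
    """Physical decay constant ``lambda = ln 2 / T_phys`` in 1/s."""
    return math.log(2.0) / d.half_life_s


def mean_electron_energy(d: DecayData) -> float:
    """Yield-weighted mean electron energy per decay, keV.

    Includes the beta continuum and conversion/Auger lines; for Lu-177 this
    is ~148 keV per decay (2.37e-14 J), the quantity that dominates the
    center-voxel energy of the Monte Carlo kernel.
    """
    if len(d.electron_energies_keV) == 0:
        raise ValueError("empty electron emission table")
    return float(np.dot(d.electron_energies_keV, d.electron_yields))


def mean_photon_energy(d: DecayData) -> float:
    """Yield-weighted mean photon energy per decay, keV."""
    return float(np.dot(d.photon_energies_keV, d.photon_yields))


@dataclass(frozen=True)
class CsdaTable:
    """Electron CSDA ranges in water, log-log interpolated."""

    E_keV: np.ndarray
    range_g_cm2: np.ndarray
    density_g_cm3: float = 1.0

    def range_mm(self, E_keV: np.ndarray | float) -> np.ndarray:
        """CSDA range in mm of unit-density water for electron energy keV."""
        E = np.clip(np.asarray(E_keV, dtype=float), self.E_keV[0], self.E_keV[-1])
        r = np.exp(
            np.interp(np.log(E), np.log(self.E_keV), np.log(self.range_g_cm2))
        )
        return r / self.density_g_cm3 * 10.0  # g/cm^2 -> cm -> mm

    def energy_from_range_mm(self, r_mm: np.ndarray | float) -> np.ndarray:
        """Inverse lookup: electron energy (keV) with the given residual range."""
        r = np.asarray(r_mm, dtype=float) * self.density_g_cm3 / 10.0
        r = np.clip(r, self.range_g_cm2[0], self.range_g_cm2[-1])
        return np.exp(
            np.interp(np.log(r), np.log(self.range_g_cm2), np.log(self.E_keV))
        )


def load_csda_table() -> CsdaTable:
    raw = json.loads(_data_text("electron_csda_water.json"))
    return CsdaTable(
        E_keV=np.asarray(raw["E_keV"], dtype=float),
        range_g_cm2=np.asarray(raw["range_g_cm2"], dtype=float),
        density_g_cm3=float(raw["density_g_cm3"]),
    )


@dataclass(frozen=True)
class PhotonAttenuation:
    """Photon mass attenuation / energy-absorption coefficients for water."""

    E_keV: np.ndarray
    mu_rho: np.ndarray
    mu_en_rho: np.ndarray
    density_g_cm3: float = 1.0

    def mu_total_per_mm(self, E_keV: np.ndarray | float) -> np.ndarray:
        """Linear attenuation coefficient (1/mm) at unit density."""
        E = np.clip(np.asarray(E_keV, dtype=float), self.E_keV[0], self.E_keV[-1])
        mu = np.exp(np.interp(np.log(E), np.log(self.E_keV), np.log(self.mu_rho)))
        return mu * self.density_g_cm3 / 10.0

    def absorption_fraction(self, E_keV: np.ndarray | float) -> np.ndarray:
        """mu_en/mu_tot — fraction of photon energy absorbed locally per interaction."""
        E = np.clip(np.asarray(E_keV, dtype=float), self.E_keV[0], self.E_keV[-1])
        mu = np.exp(np.interp(np.log(E), np.log(self.E_keV), np.log(self.mu_rho)))
        mu_en = np.exp(
            np.interp(np.log(E), np.log(self.E_keV), np.log(self.mu_en_rho))
        )
        return mu_en / mu


def load_photon_attenuation() -> PhotonAttenuation:
    raw = json.loads(_data_text("photon_attenuation_water.json"))
    return PhotonAttenuation(
        E_keV=np.asarray(raw["E_keV"], dtype=float),
        mu_rho=np.asarray(raw["mu_rho_cm2_g"], dtype=float),
        mu_en_rho=np.asarray(raw["mu_en_rho_cm2_g"], dtype=float),
        density_g_cm3=float(raw["density_g_cm3"]),
    )
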