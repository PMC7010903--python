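"""Regenerate the packaged physics tables.

Writes ``src/celldose/data/water_stopping_power.csv`` (electron collisional
stopping power of liquid water from the Berger-Seltzer formula, I = 75 eV,
density effect neglected, valid ~1 keV - 1 MeV) and
``src/celldose/data/lu177_electrons.csv`` (a Lu-177 electron emission
compilation: allowed-shape Fermi beta densities per branch plus internal
conversion and Auger lines).

The shipped CSVs are versioned fixtures; run this script only to rebuild them
after changing the source constants below.
"""
from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "celldose" / "data"

MC2_KEV = 510.99895  # electron rest energy
ALPHA_FS = 1.0 / 137.035999


def collision_stopping_power_water(energy_kev: np.ndarray) -> np.ndarray:
    """Berger-Seltzer electron collisional stopping power of water, MeV cm^2/g.

    Mean excitation energy I = 75 eV, Z/A = 0.55509.  The density-effect
    correction is omitted (< a few % below 1 MeV).
    """
    tau = np.asarray(energy_kev, dtype=float) / MC2_KEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    i_ratio = (75.0e-3 / MC2_KEV) ** 2  # (I / m c^2)^2 with I in keV
    ln_term = np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio))
    f_minus = (1.0 - beta2) * (1.0 + tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0))
    return 0.153536 * 0.55509 / beta2 * (ln_term + f_minus)


def fermi_function(z_daughter: int, energy_kev: np.ndarray) -> np.ndarray:
    """Nonrelativistic Fermi Coulomb correction for beta-minus decay."""
    e_tot = np.asarray(energy_kev, dtype=float) + MC2_KEV
    beta = np.sqrt(1.0 - (MC2_KEV / e_tot) ** 2)
    eta = ALPHA_FS * z_daughter / np.maximum(beta, 1e-9)
    x = 2.0 * math.pi * eta
    return x / (1.0 - np.exp(-x))


def allowed_beta_density(endpoint_kev: float, z_daughter: int, step_kev: float = 2.0):
    """Allowed-shape beta spectral density N(E) ~ p E_tot (Q-E)^2 F(Z,E).

    Returns (energies, density) with the density normalised to unit integral.
    """
    e = np.arange(1.0, endpoint_kev, step_kev)
    e_tot = e + MC2_KEV
    p = np.sqrt(e_tot**2 - MC2_KEV**2)
    density = p * e_tot * (endpoint_kev - e) ** 2 * fermi_function(z_daughter, e)
    density /= np.trapezoid(density, e)
    return e, density


# Lu-177 -> Hf-177 (Z_daughter = 72) beta branches: (endpoint keV, yield/decay)
BETA_BRANCHES = [
    (497.8, 0.786),
    (384.5, 0.091),
    (248.6, 0.001),
    (176.5, 0.122),
]

# Discrete electron emissions (keV, yield/decay): internal-conversion lines of
# the 112.95 and 208.37 keV transitions in Hf-177 plus grouped Auger electrons.
DISCRETE_LINES = [
    (47.6, 0.0990),   # CE-K 112.95
    (101.7, 0.0400),  # CE-L 112.95
    (110.3, 0.0100),  # CE-M 112.95
    (112.4, 0.0030),  # CE-N+ 112.95
    (143.0, 0.0077),  # CE-K 208.37
    (197.1, 0.0027),  # CE-L 208.37
    (205.8, 0.0007),  # CE-M 208.37
    (44.8, 0.0058),   # Auger-K (grouped)
    (7.3, 0.1120),    # Auger-L (grouped)
    (1.6, 1.1000),    # Auger-M+ (grouped, below the default sampling cutoff)
]


def write_stopping_power() -> Path:
    energies = np.geomspace(1.0, 1000.0, 121)
    sp = collision_stopping_power_water(energies)
    out = DATA_DIR / "water_stopping_power.csv"
    with out.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["energy_keV", "S_keV_per_um"])
        for e, s in zip(energies, sp):
            # MeV cm^2/g * rho[g/cm^3] * 0.1 -> keV/um, water rho = 1
            writer.writerow([f"{e:.6g}", f"{s * 0.1:.6g}"])
    return out


def write_emission_table() -> Path:
    out = DATA_DIR / "lu177_electrons.csv"
    with out.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["type", "energy_keV", "yield", "density", "branch"])
        for endpoint, branch_yield in BETA_BRANCHES:
            e, dens = allowed_beta_density(endpoint, z_daughter=72)
            for ei, di in zip(e, dens):
                writer.writerow(
                    ["beta", f"{ei:.2f}", f"{branch_yield:.6g}", f"{di:.6g}", f"{endpoint:g}"]
                )
        for energy, line_yield in DISCRETE_LINES:
            writer.writerow(["discrete", f"{energy:.2f}", f"{line_yield:.6g}", "", ""])
    return out


if __name__ == "__main__":
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for path in (write_stopping_power(), write_emission_table()):
        print("wrote", path)
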