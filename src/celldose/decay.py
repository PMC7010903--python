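"""Electron emission spectrum of Lu-177 and range-energy relations.

The transport engine needs two physics inputs: the electron emission spectrum
of the radionuclide (continuous beta branches plus discrete internal-conversion
and Auger lines) and the collisional stopping power of the media the electrons
cross.  Both are tabulated: a packaged Lu-177 compilation and a water
stopping-power table ship with the package, and user-supplied CSVs with the
same columns can replace either.

Energies are keV, lengths micrometres, densities g/cm^3 throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaBranch",
    "DiscreteLine",
    "EmissionSpectrum",
    "MaterialModel",
    "load_emission_spectrum",
    "sample_electron",
    "LU177_HALF_LIFE_DAYS",
    "LU177_LAMBDA_PER_H",
]

#: Physical half-life of Lu-177 in days and the decay constant in 1/h.
LU177_HALF_LIFE_DAYS = 6.647
LU177_LAMBDA_PER_H = np.log(2.0) / (LU177_HALF_LIFE_DAYS * 24.0)

_DEFAULT_CUTOFF_KEV = 3.8


class EmissionTableError(ValueError):
    """Raised when an emission or stopping-power table fails validation."""


@dataclass(frozen=True)
class BetaBranch:
    """One continuous beta branch: tabulated spectral density up to the endpoint."""

    endpoint_kev: float
    branch_yield: float  # electrons per decay, before any cutoff
    energies: np.ndarray  # keV grid
    density: np.ndarray  # probability density on the grid, unit integral

    def truncated(self, cutoff_kev: float) -> "BetaBranch | None":
        """Return the branch restricted to E >= cutoff, with reduced yield.

        Emissions below the sampling cutoff carry negligible range (< the
        resolution of the geometry) and are dropped; the surviving probability
        mass keeps its original normalisation so per-decay energy bookkeeping
        stays consistent between sampling and quadrature.
        """
        keep = self.energies >= cutoff_kev
        if keep.sum() < 2:
            return None
        e, d = self.energies[keep], self.density[keep]
        surviving = float(np.trapezoid(d, e))
        if surviving <= 0:
            return None
        return BetaBranch(self.endpoint_kev, self.branch_yield * surviving, e, d / surviving)

    @property
    def mean_energy_kev(self) -> float:
        return float(np.trapezoid(self.energies * self.density, self.energies))


@dataclass(frozen=True)
class DiscreteLine:
    energy_kev: float
    line_yield: float


@dataclass
class EmissionSpectrum:
    """Electron emission spectrum: beta branches + discrete lines.

    ``low_energy_cutoff_kev`` is applied at construction: discrete lines below
    it are removed and beta densities truncated (yields reduced accordingly),
    mirroring Monte Carlo source sampling that starts at the cutoff.  The mean
    energy emitted per decay ``delta_kev`` is computed on the same truncated
    spectrum, so the full-absorption limit S -> delta / m holds exactly for
    the sampled source.
    """

    beta_branches: list[BetaBranch]
    discrete_lines: list[DiscreteLine]
    low_energy_cutoff_kev: float = _DEFAULT_CUTOFF_KEV
    _sampler: "_SpectrumSampler | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.low_energy_cutoff_kev < 0:
            raise EmissionTableError("low-energy cutoff must be >= 0")
        self.beta_branches = [
            b
            for b in (br.truncated(self.low_energy_cutoff_kev) for br in self.beta_branches)
            if b is not None
        ]
        self.discrete_lines = [
            l for l in self.discrete_lines if l.energy_kev >= self.low_energy_cutoff_kev
        ]
        if not self.beta_branches and not self.discrete_lines:
            raise EmissionTableError("spectrum empty after applying the energy cutoff")

    @property
    def total_yield(self) -> float:
        """Electrons emitted per decay (above the cutoff)."""
        return sum(b.branch_yield for b in self.beta_branches) + sum(
            l.line_yield for l in self.discrete_lines
        )

    @property
    def delta_kev(self) -> float:
        """Mean electron energy emitted per decay (keV), by quadrature."""
        total = sum(b.branch_yield * b.mean_energy_kev for b in self.beta_branches)
        total += sum(l.line_yield * l.energy_kev for l in self.discrete_lines)
        return float(total)

    @property
    def max_energy_kev(self) -> float:
        e = [b.energies[-1] for b in self.beta_branches] + [
            l.energy_kev for l in self.discrete_lines
        ]
        return float(max(e))

    def sampler(self) -> "_SpectrumSampler":
        if self._sampler is None:
            self._sampler = _SpectrumSampler(self)
        return self._sampler


class _SpectrumSampler:
    """Vectorised inverse-CDF sampler over emission channels.

    Channels are the beta branches plus each discrete line, picked with
    probability proportional to their (cutoff-reduced) yields; beta energies
    come from the branch's tabulated inverse CDF.
    """

    def __init__(self, spectrum: EmissionSpectrum):
        yields = [b.branch_yield for b in spectrum.beta_branches] + [
            l.line_yield for l in spectrum.discrete_lines
        ]
        yields = np.asarray(yields, dtype=float)
        if not np.all(np.isfinite(yields)) or yields.sum() <= 0:
            raise EmissionTableError("all emission yields are zero")
        self.channel_prob = yields / yields.sum()
        self.n_beta = len(spectrum.beta_branches)
        self.line_energies = np.array(
            [l.energy_kev for l in spectrum.discrete_lines], dtype=float
        )
        # per-branch inverse CDF tables
        self._inv_cdf: list[tuple[np.ndarray, np.ndarray]] = []
        for b in spectrum.beta_branches:
            cdf = np.concatenate(
                ([0.0], np.cumsum(np.diff(b.energies) * 0.5 * (b.density[1:] + b.density[:-1])))
            )
            cdf /= cdf[-1]
            # strictly increasing for interp
            cdf, idx = np.unique(cdf, return_index=True)
            self._inv_cdf.append((cdf, b.energies[idx]))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        channel = rng.choice(self.channel_prob.size, size=n, p=self.channel_prob)
        energies = np.empty(n, dtype=float)
        for i in range(self.n_beta):
            mask = channel == i
            if mask.any():
                u = rng.random(mask.sum())
                cdf, e = self._inv_cdf[i]
                energies[mask] = np.interp(u, cdf, e)
        line_mask = channel >= self.n_beta
        if line_mask.any():
            energies[line_mask] = self.line_energies[channel[line_mask] - self.n_beta]
        return energies


def _packaged(name: str) -> Path:
    return Path(resources.files("celldose").joinpath("data", name))  # type: ignore[arg-type]


def load_emission_spectrum(
    path: str | Path | None = None, low_energy_cutoff_kev: float = _DEFAULT_CUTOFF_KEV
) -> EmissionSpectrum:
    """Load an electron emission table (defaults to the packaged Lu-177 one).

    The CSV needs columns ``type`` (beta|discrete), ``energy_keV``, ``yield``,
    ``density`` and, for beta rows, ``branch`` identifying the branch (rows of
    one branch share the yield and are read in energy order).
    """
    path = _packaged("lu177_electrons.csv") if path is None else Path(path)
    table = pd.read_csv(path)
    required = {"type", "energy_keV", "yield", "density"}
    if missing := required - set(table.columns):
        raise EmissionTableError(f"emission table missing columns: {sorted(missing)}")
    bad = table[~np.isfinite(table["energy_keV"]) | ~np.isfinite(table["yield"])]
    if not bad.empty:
        raise EmissionTableError(f"non-finite energy/yield in row {bad.index[0]}")
    if (table["yield"] < 0).any():
        row = int(table.index[table["yield"] < 0][0])
        raise EmissionTableError(f"negative yield in row {row}")

    branches = []
    beta = table[table["type"] == "beta"]
    if not beta.empty:
        if "branch" not in beta.columns:
            raise EmissionTableError("beta rows need a 'branch' column")
        for key, grp in beta.groupby("branch", sort=False):
            grp = grp.sort_values("energy_keV")
            dens = grp["density"].to_numpy(dtype=float)
            if (dens < 0).any():
                raise EmissionTableError(f"negative density in beta branch {key}")
            e = grp["energy_keV"].to_numpy(dtype=float)
            norm = np.trapezoid(dens, e)
            branches.append(
                BetaBranch(float(e[-1]), float(grp["yield"].iloc[0]), e, dens / norm)
            )
    lines = [
        DiscreteLine(float(r["energy_keV"]), float(r["yield"]))
        for _, r in table[table["type"] == "discrete"].iterrows()
    ]
    return EmissionSpectrum(branches, lines, low_energy_cutoff_kev)


def sample_electron(
    spectrum: EmissionSpectrum, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Draw electron energies (keV), one per emission event."""
    out = spectrum.sampler().sample(rng, 1 if size is None else int(size))
    return float(out[0]) if size is None else out


class MaterialModel:
    """A medium with a tabulated collisional stopping power and CSDA range.

    The range table is built by trapezoidal integration of 1/S(E) on a dense
    log grid; forward (``csda_range``) and inverse (``residual_energy``)
    lookups interpolate linearly on the same knots, so the round trip is exact
    to interpolation resolution.
    """

    def __init__(
        self,
        name: str,
        density_g_cm3: float,
        energies_kev: np.ndarray,
        stopping_kev_um: np.ndarray,
    ):
        energies_kev = np.asarray(energies_kev, dtype=float)
        stopping_kev_um = np.asarray(stopping_kev_um, dtype=float)
        if np.any(stopping_kev_um <= 0):
            raise EmissionTableError("stopping power must be > 0 for E > 0")
        order = np.argsort(energies_kev)
        self.name = name
        self.density_g_cm3 = float(density_g_cm3)
        self.energies_kev = energies_kev[order]
        self.stopping_kev_um = stopping_kev_um[order]
        self._build_range_table()

    def _build_range_table(self) -> None:
        e_min, e_max = self.energies_kev[0], self.energies_kev[-1]
        grid = np.geomspace(e_min / 100.0, e_max, 4000)
        # power-law extrapolation of S below the table minimum
        log_s = np.interp(
            np.log(grid),
            np.log(self.energies_kev),
            np.log(self.stopping_kev_um),
        )
        s = np.exp(log_s)
        inv = 1.0 / s
        r = np.concatenate(
            ([0.0], np.cumsum(np.diff(grid) * 0.5 * (inv[1:] + inv[:-1])))
        )
        # residual integral 0 -> grid[0], assuming S ~ E^-p locally
        p = (log_s[1] - log_s[0]) / (np.log(grid[1]) - np.log(grid[0]))
        r += grid[0] / s[0] / max(1.0 - p, 0.1)
        self._grid_e = grid
        self._grid_r = r

    # -- public API ---------------------------------------------------------
    def stopping_power(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        """Collisional stopping power (keV/um), log-log interpolated."""
        return np.exp(
            np.interp(
                np.log(np.maximum(np.asarray(energy_kev, dtype=float), self._grid_e[0])),
                np.log(self.energies_kev),
                np.log(self.stopping_kev_um),
            )
        )

    def csda_range(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        """Continuous-slowing-down range (um) at the given energy (keV)."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < 0):
            raise ValueError("energy must be >= 0")
        if np.any(e > self._grid_e[-1] * (1 + 1e-12)):
            raise ValueError(
                f"energy above table maximum {self._grid_e[-1]:.0f} keV; no extrapolation"
            )
        out = np.interp(e, self._grid_e, self._grid_r)
        out = np.where(e == 0.0, 0.0, out)
        return float(out) if np.isscalar(energy_kev) else out

    def residual_energy(self, range_um: np.ndarray | float) -> np.ndarray | float:
        """Inverse range lookup: energy (keV) whose CSDA range equals ``range_um``."""
        r = np.asarray(range_um, dtype=float)
        out = np.interp(r, self._grid_r, self._grid_e)
        out = np.where(r <= 0.0, 0.0, out)
        return float(out) if np.isscalar(range_um) else out

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, name: str, density_g_cm3: float) -> "MaterialModel":
        table = pd.read_csv(path)
        return cls(
            name,
            density_g_cm3,
            table["energy_keV"].to_numpy(),
            table["S_keV_per_um"].to_numpy(),
        )

    @classmethod
    def water(cls) -> "MaterialModel":
        return cls.from_csv(_packaged("water_stopping_power.csv"), "water", 1.0)

    @classmethod
    def lipid(cls) -> "MaterialModel":
        """Density-scaled water standing in for membrane lipid (rho 0.92)."""
        water = cls.water()
        rho = 0.92
        return cls("lipid", rho, water.energies_kev, water.stopping_kev_um * rho)
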