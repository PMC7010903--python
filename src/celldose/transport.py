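"""Straight-line CSDA Monte Carlo engine for cellular S values.

Electrons are emitted isotropically from uniform positions in a source
compartment, travel in straight lines, and lose energy continuously at the
collisional stopping-power rate of water until their CSDA range is exhausted
(no scattering, no delta rays, no straggling — the MIRDcell-class
approximation).  The energy deposited in the nucleus over each traversed chord
is the difference of residual energies at chord entry and exit obtained by
range-energy inversion.

An S value is the absorbed dose to the nucleus per decay in the source
region, Gy/(Bq s):

    S = Y * <E_dep per emission> [keV] * 1.602e-16 [J/keV] / m_N [kg]

with Y the electron yield per decay and m_N the nucleus mass (volume times
unit density).  Cross-dose to a cell inside a symmetric monolayer is scored
by reciprocity: decays are sampled in the central cell and energy is tallied
in every neighbour nucleus, which on a lattice equals the dose the central
nucleus receives from all neighbours.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import EmissionSpectrum, MaterialModel, load_emission_spectrum
from .geometry import (
    CYTOPLASM,
    GOLGI,
    MEDIUM,
    MEMBRANE,
    NUCLEUS,
    MonolayerLayout,
    TruncatedConeCell,
    WellGeometry,
    layout_monolayer,
    proximity_layout,
)

__all__ = ["SValue", "SValueSet", "TransportEngine"]

KEV_TO_J = 1.602176634e-16
UM3_TO_KG = 1.0e-15  # at unit density (g/cm^3 -> kg/um^3)


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_in_cone(
    rng: np.random.Generator, axes: np.ndarray, cos_half_angle: np.ndarray
) -> np.ndarray:
    """Uniform directions inside per-ray cones around unit ``axes``.

    ``cos_half_angle`` = -1 recovers the full sphere.
    """
    n = len(axes)
    cos_t = cos_half_angle + rng.random(n) * (1.0 - cos_half_angle)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = rng.random(n) * 2.0 * np.pi
    # orthonormal frame around each axis
    helper = np.where(np.abs(axes[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(axes, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    return (
        axes * cos_t[:, None]
        + e1 * (sin_t * np.cos(phi))[:, None]
        + e2 * (sin_t * np.sin(phi))[:, None]
    )


@dataclass(frozen=True)
class SValue:
    """A Monte Carlo S value with its standard error and provenance."""

    value: float  # Gy/(Bq s)
    stderr: float
    source: str
    target: str = NUCLEUS
    n_histories: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("S value must be >= 0")


@dataclass
class SValueSet:
    """Self and cross S values per source, plus per-day monolayer totals.

    ``cross`` is keyed by (source, layout label); ``monolayer_total`` adds the
    self and cross parts for a label (cross absent or day-1 single cells means
    cross = 0), so total = self + cross holds by construction.
    """

    self_s: dict[str, SValue] = field(default_factory=dict)
    cross: dict[tuple[str, str], SValue] = field(default_factory=dict)

    def monolayer_total(self, source: str, label: str) -> float:
        total = self.self_s[source].value
        if (source, label) in self.cross:
            total += self.cross[(source, label)].value
        return total


class TransportEngine:
    """CSDA transport bound to one emission spectrum and one medium.

    All media are transported as water: cytoplasm, Golgi, nucleus, and medium
    are water-equivalent and the lipid membrane is a zero-thickness surface,
    so it never contributes a traversal path.
    """

    def __init__(
        self,
        spectrum: EmissionSpectrum | None = None,
        material: MaterialModel | None = None,
    ):
        self.spectrum = spectrum if spectrum is not None else load_emission_spectrum()
        self.material = material if material is not None else MaterialModel.water()
        self._max_range = float(self.material.csda_range(self.spectrum.max_energy_kev))

    # ------------------------------------------------------------------
    # kernel
    # ------------------------------------------------------------------
    def chord_deposit(
        self, total_range: np.ndarray, t_in: np.ndarray, t_out: np.ndarray
    ) -> np.ndarray:
        """Energy (keV) deposited on chord [t_in, t_out] of each electron.

        ``total_range`` is (n,) CSDA ranges; ``t_in``/``t_out`` may be (n,) or
        (n, m); NaN marks a missed target.  Residual energy at path length s
        is E(range = L - s); the deposit is the entry/exit difference.
        """
        L = total_range if t_in.ndim == 1 else total_range[:, None]
        s1 = np.clip(np.nan_to_num(t_in, nan=0.0), 0.0, L)
        s2 = np.clip(np.nan_to_num(t_out, nan=0.0), 0.0, L)
        dep = self.material.residual_energy(L - s1) - self.material.residual_energy(
            L - s2
        )
        return np.where(np.isnan(t_in) | (s2 <= s1), 0.0, dep)

    def deposit_along_ray(self, origin, direction, energy_kev: float, cell) -> float:
        """Energy (keV) one electron deposits in the cell's nucleus."""
        o = np.atleast_2d(np.asarray(origin, float))
        d = np.asarray(direction, float)
        d = np.atleast_2d(d / np.linalg.norm(d))
        t1, t2 = cell.nucleus_entry_exit(o, d)
        L = np.array([self.material.csda_range(energy_kev)])
        return float(self.chord_deposit(L, t1[:, 0], t2[:, 0])[0])

    def _emit(self, rng: np.random.Generator, n: int):
        energies = self.spectrum.sampler().sample(rng, n)
        ranges = np.asarray(self.material.csda_range(energies))
        return energies, ranges, _isotropic(rng, n)

    def _gy_per_kev(self, cell) -> float:
        mass_kg = cell.nucleus_volume * UM3_TO_KG  # unit density
        return KEV_TO_J / mass_kg

    def _tally_to_svalue(
        self, cell, per_history_kev: np.ndarray, source: str, seed, meta=None
    ) -> SValue:
        n = per_history_kev.size
        y = self.spectrum.total_yield
        conv = self._gy_per_kev(cell) * y
        value = float(per_history_kev.mean()) * conv
        stderr = float(per_history_kev.std(ddof=1) / np.sqrt(n)) * conv if n > 1 else 0.0
        return SValue(value, stderr, source, NUCLEUS, n, seed, meta or {})

    # ------------------------------------------------------------------
    # S values
    # ------------------------------------------------------------------
    def self_s_value(
        self, cell, source: str, n_histories: int = 100_000, seed: int | None = 0
    ) -> SValue:
        """Self-dose S value: source and target in the same cell."""
        if cell.nucleus_volume <= 0:
            raise ValueError("zero nucleus volume")
        rng = np.random.default_rng(seed)
        origins = cell.sample_point(source, rng, n_histories)
        energies, ranges, directions = self._emit(rng, n_histories)
        t1, t2 = cell.nucleus_entry_exit(origins, directions)
        dep = self.chord_deposit(ranges, t1[:, 0], t2[:, 0])
        return self._tally_to_svalue(cell, dep, source, seed)

    def cross_s_value(
        self,
        cell,
        layout: MonolayerLayout,
        source: str,
        n_histories: int = 100_000,
        seed: int | None = 0,
        chunk: int = 4096,
    ) -> SValue:
        """Total cross-dose S value from all neighbours of a symmetric layout.

        Normalisation matches the self dose: 1 Bq s in the chosen compartment
        of *each* source cell.  Scored by reciprocity (emission from the
        central cell, tally in each translated neighbour nucleus); per-
        neighbour contributions are returned in ``meta['per_neighbor']`` and
        sum to the total exactly.
        """
        if layout.n_neighbors == 0:
            return SValue(0.0, 0.0, source, NUCLEUS, n_histories, seed,
                          {"per_neighbor": np.zeros(0), "layout_gap": layout.gap})
        rng = np.random.default_rng(seed)
        centers = layout.positions
        per_neighbor = np.zeros(len(centers))
        per_history = np.empty(n_histories)
        done = 0
        while done < n_histories:
            m = min(chunk, n_histories - done)
            origins = cell.sample_point(source, rng, m)
            energies, ranges, directions = self._emit(rng, m)
            # neighbours beyond every electron's reach cannot score
            reach = ranges.max() + float(np.max(cell.nucleus_semi_axes)) if hasattr(
                cell, "nucleus_semi_axes"
            ) else ranges.max() + cell.footprint_diameter
            r = np.hypot(centers[:, 0], centers[:, 1])
            near = r <= reach + cell.footprint_diameter
            dep = np.zeros((m, len(centers)))
            if near.any():
                t1, t2 = cell.nucleus_entry_exit(origins, directions, centers[near])
                dep[:, near] = self.chord_deposit(ranges, t1, t2)
            per_neighbor += dep.sum(axis=0)
            per_history[done : done + m] = dep.sum(axis=1)
            done += m
        conv = self._gy_per_kev(cell) * self.spectrum.total_yield
        meta = {
            "per_neighbor": per_neighbor / n_histories * conv,
            "layout_gap": layout.gap,
            "n_neighbors": layout.n_neighbors,
            "estimator": "lattice reciprocity",
        }
        return self._tally_to_svalue(cell, per_history, source, seed, meta)

    def medium_s_value(
        self,
        cell,
        well: WellGeometry,
        n_histories: int = 200_000,
        seed: int | None = 0,
        chunk: int = 65536,
    ) -> SValue:
        """S value for a source uniform in the whole medium of the well.

        Importance sampling: only decays within the maximum CSDA range of the
        nucleus can score, so source positions are drawn in a ball around the
        nucleus with a radius-uniform law (pdf 1/(4 pi r^2 R)); each history
        carries the analytic weight 4 pi r^2 R / V_well, recorded in the
        metadata.  Positions falling outside the medium cylinder contribute
        zero.
        """
        if well.volume_ml <= 0:
            return SValue(0.0, 0.0, MEDIUM, NUCLEUS, n_histories, seed,
                          {"note": "empty medium"})
        rng = np.random.default_rng(seed)
        center = cell.nucleus_center
        if hasattr(cell, "nucleus_semi_axes"):
            bound = float(np.max(cell.nucleus_semi_axes)) * 1.001
        else:  # mesh nucleus: bounding sphere of its vertices
            verts = cell.meshes[NUCLEUS].vertices
            bound = float(np.max(np.linalg.norm(verts - center, axis=1))) * 1.001
        R = self._max_range + bound
        v_well = well.volume_um3
        weighted = np.empty(n_histories)
        done = 0
        while done < n_histories:
            m = min(chunk, n_histories - done)
            radii = rng.random(m) * R
            u = _isotropic(rng, m)
            pos = center + radii[:, None] * u
            in_medium = (
                (pos[:, 2] >= 0.0)
                & (pos[:, 2] <= well.height_um)
                & (pos[:, 0] ** 2 + pos[:, 1] ** 2 <= well.radius_um**2)
            )
            # decays inside the cell body belong to cellular compartments
            if hasattr(cell, "contains"):
                try:
                    in_medium &= ~np.asarray(cell.contains(CYTOPLASM, pos)) & ~np.asarray(
                        cell.contains(NUCLEUS, pos)
                    )
                except Exception:
                    pass
            energies, ranges, _ = self._emit(rng, m)
            # direction importance: under straight-line transport only rays
            # aimed at the nucleus bounding sphere can deposit, so sample
            # within that cone and weight by its solid-angle fraction
            r_c = np.maximum(np.linalg.norm(pos - center, axis=1), 1e-9)
            cos_c = np.where(r_c > bound, np.sqrt(np.clip(1 - (bound / r_c) ** 2, 0, 1)), -1.0)
            axis = (center - pos) / r_c[:, None]
            directions = _sample_in_cone(rng, axis, cos_c)
            w_dir = 0.5 * (1.0 - cos_c)
            t1, t2 = cell.nucleus_entry_exit(pos, directions)
            dep = self.chord_deposit(ranges, t1[:, 0], t2[:, 0])
            w_pos = 4.0 * np.pi * radii**2 * R / v_well
            weighted[done : done + m] = np.where(in_medium, dep * w_pos * w_dir, 0.0)
            done += m
        meta = {
            "importance": "radius-uniform ball (weight 4*pi*r^2*R/V_well) "
            "x nucleus-cone directions (weight (1-cos)/2)",
            "R_um": R,
        }
        return self._tally_to_svalue(cell, weighted, MEDIUM, seed, meta)

    # ------------------------------------------------------------------
    # parameter sweeps
    # ------------------------------------------------------------------
    def parameter_sweep(
        self,
        sweep: str,
        values,
        source: str = CYTOPLASM,
        n_histories: int = 20_000,
        seed: int = 0,
        gap: float = 0.0,
        cutoff_um: float = 280.0,
        cell_volume: float = 3500.0,
    ) -> pd.DataFrame:
        """Run one of the standard parameter studies on truncated-cone cells.

        ``sweep`` is one of:

        * ``"volume"``: self S vs cell volume (um^3 values),
        * ``"volume_cross"``: total cross S vs cell volume, touching layout,
        * ``"source"``: self S per source compartment (values = sources),
        * ``"nucleus_shift"``: self S vs (dy, dz) nucleus displacement (um),
        * ``"gap"``: total cross S vs edge-to-edge spacing (cell diameters).
        """
        rows = []
        for i, v in enumerate(values):
            s = seed + i
            if sweep == "volume":
                cell = TruncatedConeCell.scaled_to_volume(v)
                sv = self.self_s_value(cell, source, n_histories, s)
                rows.append({"param": v, "kind": "self"})
            elif sweep == "volume_cross":
                cell = TruncatedConeCell.scaled_to_volume(v)
                lay = layout_monolayer(cell, gap, cutoff_um)
                sv = self.cross_s_value(cell, lay, source, n_histories, s)
                rows.append({"param": v, "kind": "cross"})
            elif sweep == "source":
                cell = TruncatedConeCell.scaled_to_volume(cell_volume)
                sv = self.self_s_value(cell, v, n_histories, s)
                rows.append({"param": v, "kind": "self"})
            elif sweep == "nucleus_shift":
                # shift the nucleus away from the Golgi (which stays anchored);
                # the wide-top variant leaves lateral room for the shift
                dy, dz = v
                cell = TruncatedConeCell.wide_variant(
                    cell_volume,
                    nucleus_offset=np.array([-dy, dz]),
                    golgi_follows_nucleus=False,
                )
                sv = self.self_s_value(cell, source, n_histories, s)
                rows.append({"param": f"({dy},{dz})", "kind": "self"})
            elif sweep == "gap":
                cell = TruncatedConeCell.scaled_to_volume(cell_volume)
                lay = proximity_layout(cell, v, cutoff_um)
                sv = self.cross_s_value(cell, lay, source, n_histories, s)
                rows.append({"param": v, "kind": "cross"})
            else:
                raise ValueError(f"unknown sweep {sweep!r}")
            rows[-1].update(
                sweep=sweep,
                source=sv.source,
                value=sv.value,
                stderr=sv.stderr,
                n_histories=sv.n_histories,
                seed=s,
            )
        return pd.DataFrame(rows)


def exponential_fit_r2(x: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Fit S = A exp(-b x); returns (A, b, R^2 of ln S against x)."""
    x = np.asarray(x, float)
    ln_s = np.log(np.asarray(s, float))
    b, a = np.polyfit(x, ln_s, 1)
    pred = a + b * x
    ss_res = np.sum((ln_s - pred) ** 2)
    ss_tot = np.sum((ln_s - ln_s.mean()) ** 2)
    return float(np.exp(a)), float(-b), float(1.0 - ss_res / ss_tot)
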