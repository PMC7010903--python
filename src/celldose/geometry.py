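"""Cell geometries, monolayer layouts, and the culture-well geometry.

Three cell families are supported, matching how cellular S values are usually
modelled:

* concentric/eccentric **spheres** (the MIRDcell convention),
* a **truncated-cone** constructive solid geometry: a frustum cell body with an
  oblate-ellipsoid nucleus resting near the base and a half circular torus
  Golgi wrapped around one side of the nucleus (an adherent, flattened cell),
* watertight **triangle meshes** for cytoplasm, nucleus, and Golgi.

Every cell exposes the same interface: compartment volumes, uniform point
sampling per compartment, and vectorised entry/exit distances of rays through
the (possibly translated) nucleus, which is all the straight-line transport
engine needs.  Coordinates are right-handed with z up; adherent cells sit on
the plane z = 0; lengths are micrometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "CYTOPLASM",
    "MEMBRANE",
    "NUCLEUS",
    "GOLGI",
    "MEDIUM",
    "GeometryError",
    "SphereCell",
    "TruncatedConeCell",
    "MeshCell",
    "make_sphere_cell",
    "make_truncated_cone_cell",
    "load_mesh_cell",
    "sample_point_in_compartment",
    "MonolayerLayout",
    "layout_monolayer",
    "proximity_layout",
    "cluster_layout",
    "WellGeometry",
    "build_well",
    "min_surface_distance",
]

CYTOPLASM = "Cy"
MEMBRANE = "CS"
NUCLEUS = "N"
GOLGI = "G"
MEDIUM = "M"

#: Default neighbour cutoff: the average range of Lu-177 beta electrons (um).
DEFAULT_CUTOFF_UM = 280.0


class GeometryError(ValueError):
    """Raised for invalid or degenerate cell geometry."""


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

def ellipsoid_entry_exit(
    origins: np.ndarray,
    directions: np.ndarray,
    centers: np.ndarray,
    semi_axes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit ray parameters through translated copies of one ellipsoid.

    ``origins``/``directions`` are (n, 3) (directions unit length), ``centers``
    is (m, 3).  Returns two (n, m) arrays of entry and exit distances along
    each ray; misses are NaN.  Intersections behind the origin are clipped to
    zero by the caller.
    """
    semi = np.asarray(semi_axes, dtype=float)
    d = directions / semi  # (n,3) scaled directions
    a = np.einsum("ij,ij->i", d, d)[:, None]  # (n,1)
    o = (origins[:, None, :] - centers[None, :, :]) / semi  # (n,m,3)
    b = 2.0 * np.einsum("ij,imj->im", d, o)
    c = np.einsum("imj,imj->im", o, o) - 1.0
    disc = b * b - 4.0 * a * c
    hit = disc > 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t1 = np.where(hit, (-b - sq) / (2.0 * a), np.nan)
    t2 = np.where(hit, (-b + sq) / (2.0 * a), np.nan)
    return t1, t2


def _unit_sphere_surface(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def ray_mesh_t(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    chunk: int = 2_000_000,
) -> list[np.ndarray]:
    """All ray-parameter values t >= 0 where rays cross a triangle soup.

    Vectorised Moller-Trumbore over ray x triangle pairs (chunked by memory);
    ``triangles`` is (f, 3, 3).  Returns one sorted array of crossings per
    ray.  Used for mesh containment (crossing parity) and chord extraction.
    """
    origins = np.atleast_2d(origins)
    directions = np.atleast_2d(directions)
    n, f = len(origins), len(triangles)
    e1 = triangles[:, 1] - triangles[:, 0]  # (f,3)
    e2 = triangles[:, 2] - triangles[:, 0]
    out: list[np.ndarray] = []
    rows = max(1, chunk // max(f, 1))
    for start in range(0, n, rows):
        o = origins[start : start + rows][:, None, :]  # (r,1,3)
        d = directions[start : start + rows][:, None, :]
        p = np.cross(d, e2[None, :, :])  # (r,f,3)
        det = np.einsum("rfk,fk->rf", p, e1)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - triangles[None, :, 0, :]
        u = np.einsum("rfk,rfk->rf", s, p) * inv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("rfk,rfk->rf", q, np.broadcast_to(d, q.shape)) * inv
        t = np.einsum("rfk,fk->rf", q, e2) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        for i in range(t.shape[0]):
            out.append(np.sort(t[i][hit[i]]))
    return out


def points_in_mesh(points: np.ndarray, mesh: "trimesh.Trimesh") -> np.ndarray:
    """Point-in-mesh test by crossing parity along a fixed oblique ray."""
    points = np.atleast_2d(points)
    direction = np.tile(
        np.array([[0.5773502691896258, 0.31830988618, 0.7504911]]), (len(points), 1)
    )
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    crossings = ray_mesh_t(points, direction, mesh.triangles)
    return np.array([len(t) % 2 == 1 for t in crossings])


def min_surface_distance(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Brute-force minimum distance between two surface point clouds."""
    d2 = np.min(
        np.sum((points_a[:, None, :] - points_b[None, :, :]) ** 2, axis=-1)
    )
    return float(np.sqrt(d2))


# ---------------------------------------------------------------------------
# sphere cell (MIRDcell convention)
# ---------------------------------------------------------------------------

@dataclass
class SphereCell:
    """Spherical cell with a (possibly eccentric) spherical nucleus."""

    cell_radius: float
    nucleus_radius: float
    nucleus_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    shape_kind: str = "sphere"

    def __post_init__(self) -> None:
        self.nucleus_offset = np.asarray(self.nucleus_offset, dtype=float)
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise GeometryError("need 0 < nucleus radius < cell radius")
        if (
            np.linalg.norm(self.nucleus_offset) + self.nucleus_radius
            >= self.cell_radius
        ):
            raise GeometryError("nucleus protrudes from the cell: N not inside cell")
        # adherent convention: sphere tangent to z = 0
        self.center = np.array([0.0, 0.0, self.cell_radius])
        self.nucleus_center = self.center + self.nucleus_offset
        self.nucleus_semi_axes = np.full(3, self.nucleus_radius)

    @property
    def nucleus_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.nucleus_radius**3

    @property
    def cell_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.cell_radius**3

    @property
    def footprint_diameter(self) -> float:
        return 2.0 * self.cell_radius

    def compartment_volume(self, compartment: str) -> float:
        if compartment == NUCLEUS:
            return self.nucleus_volume
        if compartment == CYTOPLASM:
            return self.cell_volume - self.nucleus_volume
        if compartment == MEMBRANE:
            return 0.0  # zero-thickness surface source
        raise GeometryError(f"sphere cell has no compartment {compartment!r}")

    def contains(self, compartment: str, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        in_cell = np.sum((points - self.center) ** 2, axis=1) <= self.cell_radius**2
        in_nuc = (
            np.sum((points - self.nucleus_center) ** 2, axis=1)
            <= self.nucleus_radius**2
        )
        if compartment == NUCLEUS:
            return in_nuc
        if compartment == CYTOPLASM:
            return in_cell & ~in_nuc
        raise GeometryError(f"no containment predicate for {compartment!r}")

    def sample_point(
        self, compartment: str, rng: np.random.Generator, n: int
    ) -> np.ndarray:
        if compartment == MEMBRANE:
            return self.center + self.cell_radius * _unit_sphere_surface(rng, n)
        if compartment == NUCLEUS:
            u = _unit_sphere_surface(rng, n) * rng.random((n, 1)) ** (1 / 3)
            return self.nucleus_center + self.nucleus_radius * u
        if compartment == CYTOPLASM:
            return _rejection_sample(
                lambda k: self.center
                + self.cell_radius * _unit_sphere_surface(rng, k) * rng.random((k, 1)) ** (1 / 3),
                lambda p: ~self.contains(NUCLEUS, p),
                n,
            )
        raise GeometryError(f"cannot sample compartment {compartment!r}")

    def nucleus_entry_exit(self, origins, directions, centers=None):
        centers = (
            self.nucleus_center[None, :]
            if centers is None
            else np.atleast_2d(centers) + self.nucleus_center
        )
        return ellipsoid_entry_exit(origins, directions, centers, self.nucleus_semi_axes)

    def validate(self, rng: np.random.Generator | None = None) -> None:
        pass  # closed-form constraints already enforced in __post_init__


def _rejection_sample(proposal, predicate, n: int, max_batches: int = 10000) -> np.ndarray:
    out: list[np.ndarray] = []
    have = 0
    tried = 0
    for _ in range(max_batches):
        batch = proposal(max(n, 1024))
        keep = batch[predicate(batch)]
        tried += len(batch)
        out.append(keep)
        have += len(keep)
        if have >= n:
            break
        if tried > 1e4 and have / tried < 1e-4:
            raise GeometryError("rejection sampling acceptance < 1e-4: degenerate geometry")
    else:
        raise GeometryError("rejection sampling failed to converge")
    return np.concatenate(out)[:n]


# ---------------------------------------------------------------------------
# truncated-cone CSG cell
# ---------------------------------------------------------------------------

@dataclass
class TruncatedConeCell:
    """Adherent cell: frustum body + ellipsoid nucleus + half-torus Golgi.

    The frustum stands on z = 0 with ``base_radius`` at the bottom and
    ``top_radius`` at ``height``.  The nucleus is an oblate ellipsoid with
    semi-axes ``nucleus_semi_axes`` = (a, b, c) centred at
    (0, nucleus_offset_y, c + nucleus_clearance + nucleus_offset_z).  The
    Golgi is the half of a circular torus (ring radius ``golgi_ring_radius``,
    tube radius ``golgi_tube_radius``) on the +y side of the nucleus at height
    ``golgi_center_z``; the ring radius is solved at construction so the
    minimum Golgi-nucleus surface distance equals ``golgi_min_distance``.
    """

    base_radius: float
    top_radius: float
    height: float
    nucleus_semi_axes: np.ndarray = field(default_factory=lambda: np.array([8.2, 8.2, 3.73]))
    nucleus_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (y, z)
    nucleus_clearance: float = 0.3
    golgi_tube_radius: float = 1.0
    golgi_center_z: float | None = None
    golgi_min_distance: float = 1.0
    golgi_follows_nucleus: bool = True
    shape_kind: str = "truncated_cone"

    def __post_init__(self) -> None:
        if not 0 < self.top_radius < self.base_radius:
            raise GeometryError("need 0 < top radius < base radius")
        if self.height <= 0:
            raise GeometryError("height must be > 0")
        self.nucleus_semi_axes = np.asarray(self.nucleus_semi_axes, dtype=float)
        a, b, c = self.nucleus_semi_axes
        off_y, off_z = np.asarray(self.nucleus_offset, dtype=float)
        self.nucleus_center = np.array(
            [0.0, off_y, c + self.nucleus_clearance + off_z]
        )
        # Golgi anchor: follows the nucleus by default; for nucleus-placement
        # studies the Golgi stays at the unshifted position so the shift
        # changes the Golgi-nucleus separation.
        self._golgi_anchor = (
            self.nucleus_center
            if self.golgi_follows_nucleus
            else np.array([0.0, 0.0, c + self.nucleus_clearance])
        )
        if self.golgi_center_z is None:
            # default: tube centre low on the nucleus flank, fully above base
            self.golgi_center_z = max(self.golgi_tube_radius + 0.5, 0.55 * c)
        self._check_nucleus_inside()
        self._place_golgi()
        self._validate_golgi()

    # frustum radius at height z
    def _radius_at(self, z: np.ndarray | float) -> np.ndarray | float:
        return self.base_radius - (self.base_radius - self.top_radius) * (
            np.asarray(z) / self.height
        )

    def _check_nucleus_inside(self) -> None:
        a, b, c = self.nucleus_semi_axes
        zc = self.nucleus_center[2]
        if zc - c < -1e-9 or zc + c > self.height + 1e-9:
            raise GeometryError("nucleus not inside cell: N protrudes vertically")
        z = np.linspace(zc - c, zc + c, 201)
        lateral = np.sqrt(np.maximum(0.0, 1.0 - ((z - zc) / c) ** 2))
        reach = np.abs(self.nucleus_center[1]) + max(a, b) * lateral
        if np.any(reach > self._radius_at(z) + 1e-9):
            raise GeometryError("nucleus not inside cell: N crosses the lateral surface")

    def _golgi_clearance_profile(self, ring_radius: float) -> float:
        """Min horizontal gap between the torus tube and the nucleus surface."""
        a, b, c = self.nucleus_semi_axes
        zc = self._golgi_anchor[2]
        zg = self.golgi_center_z
        z = np.linspace(zg - self.golgi_tube_radius, zg + self.golgi_tube_radius, 101)
        tube_in = ring_radius - np.sqrt(
            np.maximum(0.0, self.golgi_tube_radius**2 - (z - zg) ** 2)
        )
        frac = np.clip(1.0 - ((z - zc) / c) ** 2, 0.0, None)
        nuc_out = max(a, b) * np.sqrt(frac)
        return float(np.min(tube_in - nuc_out))

    def _place_golgi(self) -> None:
        a, b, c = self.nucleus_semi_axes
        ring = max(a, b) + self.golgi_min_distance + self.golgi_tube_radius
        # coarse pass on the horizontal-gap profile ...
        for _ in range(8):
            gap = self._golgi_clearance_profile(ring)
            err = self.golgi_min_distance - gap
            if abs(err) < 1e-3:
                break
            ring += err
        # ... then refine against the true 3D surface distance (the nearest
        # approach of tube and oblate nucleus is generally oblique)
        rng = np.random.default_rng(12345)
        nuc = self._golgi_anchor + _unit_sphere_surface(rng, 4000) * self.nucleus_semi_axes
        for _ in range(6):
            self.golgi_ring_radius = ring
            self.golgi_center = np.array([0.0, self._golgi_anchor[1], self.golgi_center_z])
            d = min_surface_distance(self._golgi_surface(rng, 2000), nuc)
            err = self.golgi_min_distance - d
            if err < 0.02:
                break
            ring += err + 0.02
        self.golgi_ring_radius = ring
        self.golgi_center = np.array(
            [0.0, self._golgi_anchor[1], self.golgi_center_z]
        )

    def _validate_golgi(self) -> None:
        if self.golgi_center_z - self.golgi_tube_radius < -1e-9:
            raise GeometryError("Golgi below the adhesion plane: G not inside Cy")
        outer = self.golgi_ring_radius + self.golgi_tube_radius
        z_lo = self.golgi_center_z - self.golgi_tube_radius
        z_hi = self.golgi_center_z + self.golgi_tube_radius
        reach = abs(self.golgi_center[1]) + outer
        if reach > min(self._radius_at(z_lo), self._radius_at(z_hi)) or z_hi > self.height:
            raise GeometryError("Golgi does not fit inside the cell: G crosses Cy boundary")

    # -- volumes ------------------------------------------------------------
    @property
    def cell_volume(self) -> float:
        rb, rt = self.base_radius, self.top_radius
        return np.pi * self.height * (rb**2 + rb * rt + rt**2) / 3.0

    @property
    def nucleus_volume(self) -> float:
        a, b, c = self.nucleus_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def golgi_volume(self) -> float:
        return np.pi**2 * self.golgi_ring_radius * self.golgi_tube_radius**2

    @property
    def footprint_diameter(self) -> float:
        return 2.0 * self.base_radius

    def compartment_volume(self, compartment: str) -> float:
        if compartment == NUCLEUS:
            return self.nucleus_volume
        if compartment == GOLGI:
            return self.golgi_volume
        if compartment == CYTOPLASM:
            return self.cell_volume - self.nucleus_volume - self.golgi_volume
        if compartment == MEMBRANE:
            return 0.0
        raise GeometryError(f"unknown compartment {compartment!r}")

    # -- predicates ---------------------------------------------------------
    def _in_frustum(self, p: np.ndarray) -> np.ndarray:
        z = p[:, 2]
        ok_z = (z >= 0.0) & (z <= self.height)
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return ok_z & (r2 <= np.asarray(self._radius_at(np.clip(z, 0, self.height))) ** 2)

    def _in_nucleus(self, p: np.ndarray) -> np.ndarray:
        u = (p - self.nucleus_center) / self.nucleus_semi_axes
        return np.sum(u * u, axis=1) <= 1.0

    def _in_golgi(self, p: np.ndarray) -> np.ndarray:
        rel = p - self.golgi_center
        on_arc = rel[:, 1] >= 0.0  # half torus on the +y side
        s = np.sqrt(rel[:, 0] ** 2 + rel[:, 1] ** 2)
        d2 = (s - self.golgi_ring_radius) ** 2 + rel[:, 2] ** 2
        return on_arc & (d2 <= self.golgi_tube_radius**2)

    def contains(self, compartment: str, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        if compartment == NUCLEUS:
            return self._in_nucleus(p)
        if compartment == GOLGI:
            return self._in_golgi(p)
        if compartment == CYTOPLASM:
            return self._in_frustum(p) & ~self._in_nucleus(p) & ~self._in_golgi(p)
        raise GeometryError(f"no containment predicate for {compartment!r}")

    # -- sampling -----------------------------------------------------------
    def _sample_frustum(self, rng: np.random.Generator, n: int) -> np.ndarray:
        def proposal(k: int) -> np.ndarray:
            z = rng.random(k) * self.height
            keep = rng.random(k) <= (np.asarray(self._radius_at(z)) / self.base_radius) ** 2
            z = z[keep]
            m = len(z)
            phi = rng.random(m) * 2 * np.pi
            r = np.asarray(self._radius_at(z)) * np.sqrt(rng.random(m))
            return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

        return _rejection_sample(proposal, lambda p: np.ones(len(p), bool), n)

    def sample_point(
        self, compartment: str, rng: np.random.Generator, n: int
    ) -> np.ndarray:
        if compartment == CYTOPLASM:
            return _rejection_sample(
                lambda k: self._sample_frustum(rng, k),
                lambda p: ~self._in_nucleus(p) & ~self._in_golgi(p),
                n,
            )
        if compartment == NUCLEUS:
            u = _unit_sphere_surface(rng, n) * rng.random((n, 1)) ** (1 / 3)
            return self.nucleus_center + u * self.nucleus_semi_axes
        if compartment == GOLGI:
            return self._sample_golgi(rng, n)
        if compartment == MEMBRANE:
            return self._sample_membrane(rng, n)
        raise GeometryError(f"cannot sample compartment {compartment!r}")

    def _sample_golgi(self, rng: np.random.Generator, n: int) -> np.ndarray:
        def proposal(k: int) -> np.ndarray:
            theta = (rng.random(k) - 0.5) * np.pi  # angle from +y axis, half arc
            rho = self.golgi_tube_radius * np.sqrt(rng.random(k))
            psi = rng.random(k) * 2 * np.pi
            keep = rng.random(k) <= (
                (self.golgi_ring_radius + rho * np.cos(psi))
                / (self.golgi_ring_radius + self.golgi_tube_radius)
            )
            theta, rho, psi = theta[keep], rho[keep], psi[keep]
            s = self.golgi_ring_radius + rho * np.cos(psi)
            x = s * np.sin(theta)
            y = s * np.cos(theta)
            z = rho * np.sin(psi)
            return self.golgi_center + np.column_stack([x, y, z])

        return _rejection_sample(proposal, lambda p: np.ones(len(p), bool), n)

    def _sample_membrane(self, rng: np.random.Generator, n: int) -> np.ndarray:
        rb, rt, h = self.base_radius, self.top_radius, self.height
        slant = np.hypot(h, rb - rt)
        areas = np.array([np.pi * rb**2, np.pi * rt**2, np.pi * (rb + rt) * slant])
        which = rng.choice(3, size=n, p=areas / areas.sum())
        out = np.empty((n, 3))
        for idx, (radius, z) in enumerate([(rb, 0.0), (rt, h)]):
            m = which == idx
            k = int(m.sum())
            phi = rng.random(k) * 2 * np.pi
            r = radius * np.sqrt(rng.random(k))
            out[m] = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.full(k, z)])
        m = which == 2
        k = int(m.sum())
        # lateral: area element ~ r(z) dz -> CDF quadratic in z
        u = rng.random(k)
        if abs(rb - rt) < 1e-12:
            z = u * h
        else:
            # invert  integral of r(z) dz
            aa = -(rb - rt) / (2 * h)
            z = (-rb + np.sqrt(rb**2 + 4 * aa * u * (rb + rt) * h / 2)) / (2 * aa)
        r = np.asarray(self._radius_at(z))
        phi = rng.random(k) * 2 * np.pi
        out[m] = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        return out

    def nucleus_entry_exit(self, origins, directions, centers=None):
        centers = (
            self.nucleus_center[None, :]
            if centers is None
            else np.atleast_2d(centers) + self.nucleus_center
        )
        return ellipsoid_entry_exit(origins, directions, centers, self.nucleus_semi_axes)

    def validate(self, rng: np.random.Generator | None = None, n: int = 4000) -> None:
        """Dense-sampling check of the containment hierarchy and d(G-N)."""
        rng = np.random.default_rng(0) if rng is None else rng
        nuc_surface = self.nucleus_center + _unit_sphere_surface(rng, n) * self.nucleus_semi_axes
        if not np.all(self._in_frustum(nuc_surface)):
            raise GeometryError("nucleus surface escapes the cell body: N not in cell")
        golgi_pts = self._sample_golgi(rng, n)
        if not np.all(self._in_frustum(golgi_pts)):
            raise GeometryError("Golgi escapes the cell body: G not in Cy")
        if np.any(self._in_nucleus(golgi_pts)):
            raise GeometryError("Golgi overlaps the nucleus: G and N not disjoint")
        d = min_surface_distance(self._golgi_surface(rng, 1500), nuc_surface)
        if self.golgi_follows_nucleus and d < self.golgi_min_distance - 0.15:
            raise GeometryError(
                f"Golgi-nucleus distance {d:.2f} um below requested "
                f"{self.golgi_min_distance:.2f} um"
            )

    def _golgi_surface(self, rng: np.random.Generator, n: int) -> np.ndarray:
        theta = (rng.random(n) - 0.5) * np.pi
        psi = rng.random(n) * 2 * np.pi
        s = self.golgi_ring_radius + self.golgi_tube_radius * np.cos(psi)
        x = s * np.sin(theta)
        y = s * np.cos(theta)
        z = self.golgi_tube_radius * np.sin(psi)
        return self.golgi_center + np.column_stack([x, y, z])

    # -- the default family -------------------------------------------------
    @classmethod
    def reference(cls) -> "TruncatedConeCell":
        """Average-size adherent cell: ~3500 um^3 body, ~1050 um^3 nucleus.

        A flattened, spread morphology (30 um footprint, ~9 um tall) with an
        oblate nucleus, the shape regime of adherent U2OS-like cells.
        """
        rb, rt = 15.0, 7.0
        height = 3.0 * 3500.0 / (np.pi * (rb**2 + rb * rt + rt**2))
        return cls(base_radius=rb, top_radius=rt, height=height)

    @classmethod
    def wide_variant(cls, cell_volume: float = 3500.0, **overrides) -> "TruncatedConeCell":
        """Same volumes as the reference but with a shallower lateral slope.

        Used for nucleus-placement studies: the wider top leaves room to
        displace the nucleus laterally by a few um without it crossing the
        cell boundary.
        """
        rb, rt = 15.0, 11.0
        height = 3.0 * cell_volume / (np.pi * (rb**2 + rb * rt + rt**2))
        c = (height - 0.3) / 2.0
        vn = 0.30016 * cell_volume  # nucleus/cell volume ratio of the family
        a = np.sqrt(3.0 * vn / (4.0 * np.pi * c))
        params = dict(
            base_radius=rb,
            top_radius=rt,
            height=height,
            nucleus_semi_axes=np.array([a, a, c]),
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def scaled_to_volume(cls, cell_volume: float, **overrides) -> "TruncatedConeCell":
        """Uniformly scaled copy of the reference cell with the given volume.

        Uniform scaling keeps the family self-similar, so cell volumes
        1900-5500 um^3 map onto nucleus volumes ~575-1665 um^3 — the ranges
        observed for the imaged cell sample.
        """
        ref = cls.reference()
        s = (cell_volume / ref.cell_volume) ** (1.0 / 3.0)
        params = dict(
            base_radius=ref.base_radius * s,
            top_radius=ref.top_radius * s,
            height=ref.height * s,
            nucleus_semi_axes=ref.nucleus_semi_axes * s,
            nucleus_clearance=ref.nucleus_clearance * s,
            golgi_tube_radius=ref.golgi_tube_radius * s,
            golgi_center_z=ref.golgi_center_z * s,
            golgi_min_distance=ref.golgi_min_distance * s,
        )
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# triangle-mesh cell
# ---------------------------------------------------------------------------

class MeshCell:
    """Cell built from watertight triangle meshes (units um).

    The membrane is the outward shell of the cytoplasm surface, treated as a
    zero-thickness surface source; volumes come from the divergence theorem
    (signed mesh volume).
    """

    shape_kind = "mesh"

    def __init__(
        self,
        cytoplasm: trimesh.Trimesh,
        nucleus: trimesh.Trimesh,
        golgi: trimesh.Trimesh | None = None,
    ):
        self.meshes = {CYTOPLASM: cytoplasm, NUCLEUS: nucleus}
        if golgi is not None:
            self.meshes[GOLGI] = golgi
        for name, mesh in self.meshes.items():
            if not mesh.is_watertight:
                raise GeometryError(f"mesh for {name!r} is not watertight")
            if mesh.volume <= 0:
                mesh.invert()
        self._validate_containment()

    def _validate_containment(self) -> None:
        cyto = self.meshes[CYTOPLASM]
        if not points_in_mesh(self.meshes[NUCLEUS].vertices, cyto).all():
            raise GeometryError("nucleus not fully inside the cell mesh")
        if GOLGI in self.meshes:
            g = self.meshes[GOLGI]
            if not points_in_mesh(g.vertices, cyto).all():
                raise GeometryError("Golgi not fully inside the cell mesh")
            if points_in_mesh(g.vertices, self.meshes[NUCLEUS]).any():
                raise GeometryError("Golgi overlaps the nucleus")

    @property
    def cell_volume(self) -> float:
        return float(self.meshes[CYTOPLASM].volume)

    @property
    def nucleus_volume(self) -> float:
        return float(self.meshes[NUCLEUS].volume)

    @property
    def nucleus_center(self) -> np.ndarray:
        return np.asarray(self.meshes[NUCLEUS].center_mass)

    @property
    def footprint_diameter(self) -> float:
        extents = self.meshes[CYTOPLASM].extents
        return float(max(extents[0], extents[1]))

    def compartment_volume(self, compartment: str) -> float:
        if compartment == MEMBRANE:
            return 0.0
        if compartment == CYTOPLASM:
            v = self.cell_volume - self.nucleus_volume
            if GOLGI in self.meshes:
                v -= self.meshes[GOLGI].volume
            return float(v)
        if compartment in self.meshes:
            return float(self.meshes[compartment].volume)
        raise GeometryError(f"unknown compartment {compartment!r}")

    def contains(self, compartment: str, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        if compartment == CYTOPLASM:
            inside = points_in_mesh(p, self.meshes[CYTOPLASM])
            inside &= ~points_in_mesh(p, self.meshes[NUCLEUS])
            if GOLGI in self.meshes:
                inside &= ~points_in_mesh(p, self.meshes[GOLGI])
            return inside
        return points_in_mesh(p, self.meshes[compartment])

    def sample_point(
        self, compartment: str, rng: np.random.Generator, n: int
    ) -> np.ndarray:
        if compartment == MEMBRANE:
            pts, _ = trimesh.sample.sample_surface(
                self.meshes[CYTOPLASM], n, seed=int(rng.integers(2**31))
            )
            return np.asarray(pts, dtype=float)
        mesh = self.meshes[CYTOPLASM if compartment == CYTOPLASM else compartment]

        def proposal(k: int) -> np.ndarray:
            lo, hi = mesh.bounds
            return lo + rng.random((k, 3)) * (hi - lo)

        return _rejection_sample(proposal, lambda p: self.contains(compartment, p), n)

    def nucleus_entry_exit(self, origins, directions, centers=None):
        """Ray/nucleus-mesh chords; supports translated copies via ``centers``.

        For non-convex nuclei the outermost crossing pair is used (a convex-
        chord approximation; the gently perturbed synthetic nuclei are near
        convex, so re-entrant rays are rare).
        """
        nucleus = self.meshes[NUCLEUS]
        centers = np.zeros((1, 3)) if centers is None else np.atleast_2d(centers)
        n, m = len(origins), len(centers)
        t1 = np.full((n, m), np.nan)
        t2 = np.full((n, m), np.nan)
        for j, c in enumerate(centers):
            crossings = ray_mesh_t(origins - c, directions, nucleus.triangles)
            for i, ts in enumerate(crossings):
                if len(ts) >= 2:
                    t1[i, j], t2[i, j] = ts[0], ts[-1]
                elif len(ts) == 1:  # origin inside the nucleus
                    t1[i, j], t2[i, j] = 0.0, ts[0]
        return t1, t2

    def validate(self, rng: np.random.Generator | None = None) -> None:
        self._validate_containment()


# ---------------------------------------------------------------------------
# spec-level constructors
# ---------------------------------------------------------------------------

def make_sphere_cell(
    cell_radius: float, nucleus_radius: float, nucleus_offset=(0.0, 0.0, 0.0)
) -> SphereCell:
    return SphereCell(cell_radius, nucleus_radius, np.asarray(nucleus_offset, float))


def make_truncated_cone_cell(
    base_radius: float,
    top_radius: float,
    height: float,
    nucleus_semi_axes=(8.2, 8.2, 3.73),
    nucleus_offset=(0.0, 0.0),
    golgi_tube_radius: float = 1.0,
    golgi_min_distance: float = 1.0,
    **kwargs,
) -> TruncatedConeCell:
    return TruncatedConeCell(
        base_radius=base_radius,
        top_radius=top_radius,
        height=height,
        nucleus_semi_axes=np.asarray(nucleus_semi_axes, float),
        nucleus_offset=np.asarray(nucleus_offset, float),
        golgi_tube_radius=golgi_tube_radius,
        golgi_min_distance=golgi_min_distance,
        **kwargs,
    )


def load_mesh_cell(
    cytoplasm_path: str | Path,
    nucleus_path: str | Path,
    golgi_path: str | Path | None = None,
) -> MeshCell:
    def _load(path):
        mesh = trimesh.load_mesh(path)
        if isinstance(mesh, trimesh.Scene):
            mesh = mesh.to_mesh()
        return mesh

    return MeshCell(
        _load(cytoplasm_path),
        _load(nucleus_path),
        _load(golgi_path) if golgi_path is not None else None,
    )


def sample_point_in_compartment(
    cell, compartment: str, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Uniform point(s) in a compartment volume (or on the membrane surface)."""
    return cell.sample_point(compartment, rng, n)


# ---------------------------------------------------------------------------
# layouts and the well
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonolayerLayout:
    """Neighbour positions of a hexagonal monolayer around a target cell at 0."""

    positions: np.ndarray  # (m, 3) neighbour centres, target excluded
    pitch: float  # centre-to-centre distance, um
    gap: float  # edge-to-edge spacing in cell diameters
    cutoff_um: float

    @property
    def n_neighbors(self) -> int:
        return len(self.positions)


def _hex_lattice(pitch: float, cutoff: float) -> np.ndarray:
    k = int(np.ceil(cutoff / (pitch * np.sqrt(3) / 2))) + 1
    i, j = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
    x = pitch * (i + 0.5 * j)
    y = pitch * (np.sqrt(3) / 2) * j
    pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = (r <= cutoff) & (r > 1e-9)
    return pts[keep]


def layout_monolayer(cell, gap: float = 0.0, cutoff_um: float = DEFAULT_CUTOFF_UM) -> MonolayerLayout:
    """Hexagonal monolayer of identical cells; ``gap`` in cell diameters.

    gap = 0 means touching footprints (pitch = one diameter); all neighbours
    whose centres lie within ``cutoff_um`` of the target are enumerated.
    """
    if gap < 0:
        raise GeometryError("gap must be >= 0")
    pitch = cell.footprint_diameter * (1.0 + gap)
    return MonolayerLayout(_hex_lattice(pitch, cutoff_um), pitch, gap, cutoff_um)


def proximity_layout(
    cell, gap: float, reference_cutoff_um: float = DEFAULT_CUTOFF_UM
) -> MonolayerLayout:
    """Monolayer for the cell-proximity study: fixed total cell count.

    The study keeps the number of surrounding cells constant across spacings
    (the count is set by the electron range for the touching reference), so
    the spaced layout is a scaled copy of the touching lattice rather than a
    re-enumeration within a fixed radius.
    """
    return layout_monolayer(cell, gap, reference_cutoff_um * (1.0 + gap))


def cluster_layout(cell, n_cells: int) -> MonolayerLayout:
    """Touching hexagonal cluster of ``n_cells``; neighbours of the centre cell."""
    if n_cells < 1:
        raise GeometryError("cluster needs at least one cell")
    pitch = cell.footprint_diameter
    if n_cells == 1:
        return MonolayerLayout(np.empty((0, 3)), pitch, 0.0, 0.0)
    lattice = _hex_lattice(pitch, pitch * (2 + int(np.sqrt(n_cells))))
    order = np.argsort(np.hypot(lattice[:, 0], lattice[:, 1]), kind="stable")
    picked = lattice[order[: n_cells - 1]]
    return MonolayerLayout(picked, pitch, 0.0, float(np.hypot(picked[:, 0], picked[:, 1]).max()))


@dataclass(frozen=True)
class WellGeometry:
    """Cylindrical culture well filled with medium; cell at the bottom centre."""

    radius_mm: float
    volume_ml: float

    @property
    def height_mm(self) -> float:
        return self.volume_ml * 1e3 / (np.pi * self.radius_mm**2)  # 1 ml = 1e3 mm^3

    @property
    def radius_um(self) -> float:
        return self.radius_mm * 1e3

    @property
    def height_um(self) -> float:
        return self.height_mm * 1e3

    @property
    def volume_um3(self) -> float:
        return self.volume_ml * 1e12


#: Inner radius of a standard 12-well culture plate well.
DEFAULT_WELL_RADIUS_MM = 11.05


def build_well(volume_ml: float = 1.0, well_radius_mm: float = DEFAULT_WELL_RADIUS_MM) -> WellGeometry:
    if volume_ml <= 0 or well_radius_mm <= 0:
        raise GeometryError("well volume and radius must be > 0")
    return WellGeometry(well_radius_mm, volume_ml)
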