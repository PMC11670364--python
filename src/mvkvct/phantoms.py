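"""Procedural 2-D phantoms and exact ray tracing through them.

Two study phantoms are provided: an image-quality (IQ) phantom — a 40-cm
soft-tissue cylinder holding seven 3-cm bone inserts whose densities span
1.0-2.2 g/cm^3 on a ring — and a procedural torso slice (elliptical body,
lungs, spine, lateral rib bones) that emulates the central-ray thickness
statistics of an anthropomorphic phantom: tissue-equivalent paths of roughly
18-32 cm and bone-equivalent paths up to ~5 cm.

Phantoms are lists of geometric primitives in painter's order (later
primitives override earlier ones), so line integrals are exact chord
computations.  Path lengths are reported as *basis-equivalent* thicknesses:
a chord L through a primitive of density rho contributes ``L * rho /
rho_basis`` to its basis material (tissue basis 1.06 g/cm^3, bone basis
1.85 g/cm^3), the convention used by the decomposition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .physics import ParameterError, load_material

__all__ = [
    "Primitive",
    "Phantom2D",
    "ThicknessProfile",
    "BASIS_DENSITIES",
    "make_iq_phantom",
    "make_torso_phantom",
    "basis_thickness_profiles",
    "IQ_INSERT_DENSITIES",
]

#: (tissue, bone) basis densities, g/cm^3
BASIS_DENSITIES = (1.06, 1.85)
#: which basis index each phantom material contributes to
MATERIAL_BASIS_INDEX = {"tissue": 0, "water": 0, "bone": 1}

IQ_INSERT_DENSITIES = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2)


@dataclass(frozen=True)
class Primitive:
    """An axis-alignable elliptical primitive (circle = equal radii)."""

    shape: str               # "circle" | "ellipse"
    center: tuple            # (x, y), cm
    radii: tuple             # (rx, ry), cm
    material: str            # key of MATERIAL_BASIS_INDEX
    density: float           # g/cm^3
    angle_deg: float = 0.0   # rotation of the ellipse axes

    def __post_init__(self):
        if self.shape not in ("circle", "ellipse"):
            raise ParameterError(f"unsupported primitive shape {self.shape!r}")
        if self.density <= 0:
            raise ParameterError("primitive density must be positive")
        if min(self.radii) <= 0:
            raise ParameterError("primitive radii must be positive")
        if self.material not in MATERIAL_BASIS_INDEX:
            raise ParameterError(f"unknown phantom material {self.material!r}")


@dataclass(frozen=True)
class Phantom2D:
    """A 2-D phantom: primitives in painter's order plus a field of view."""

    primitives: tuple
    extent_cm: float = 50.0

    def __post_init__(self):
        half = self.extent_cm / 2.0
        for p in self.primitives:
            if (abs(p.center[0]) + max(p.radii) > half + 1e-9
                    or abs(p.center[1]) + max(p.radii) > half + 1e-9):
                raise ParameterError(
                    f"primitive at {p.center} extends beyond the field of view")

    # -- ray tracing --------------------------------------------------------

    def basis_path_lengths(self, origins: np.ndarray, directions: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Exact basis mass thicknesses A_j (g/cm^2) along each ray.

        ``origins`` and ``directions`` have shape (n, 2); directions need not
        be normalized (lengths are measured in cm along the unit direction).
        Painter's order is honored by subtracting, from each primitive's
        chord, its overlap with every later primitive; this is exact when
        the later primitives overlapping it are mutually disjoint (true for
        the bundled phantoms).
        """
        o = np.atleast_2d(np.asarray(origins, float))
        d = np.atleast_2d(np.asarray(directions, float))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        n = o.shape[0]
        prims = self.primitives
        t_in = np.zeros((len(prims), n))
        t_out = np.zeros((len(prims), n))
        for k, p in enumerate(prims):
            t_in[k], t_out[k] = _ray_ellipse_interval(p, o, d)
        a = np.zeros((2, n))
        for k, p in enumerate(prims):
            length = t_out[k] - t_in[k]
            for l in range(k + 1, len(prims)):
                lo = np.maximum(t_in[k], t_in[l])
                hi = np.minimum(t_out[k], t_out[l])
                length -= np.clip(hi - lo, 0.0, None)
            length = np.clip(length, 0.0, None)
            a[MATERIAL_BASIS_INDEX[p.material]] += length * p.density
        return a[0], a[1]

    def basis_equivalent_thicknesses(self, origins, directions
                                     ) -> tuple[np.ndarray, np.ndarray]:
        """Basis-equivalent thicknesses in cm (A_j / rho_basis,j)."""
        a_t, a_b = self.basis_path_lengths(origins, directions)
        return a_t / BASIS_DENSITIES[0], a_b / BASIS_DENSITIES[1]

    # -- rasterization ------------------------------------------------------

    def rasterize(self, n_pixels: int = 512, value: str = "density",
                  energy_kev: float = 80.0) -> np.ndarray:
        """Paint the phantom onto an n x n grid over the field of view.

        ``value``: 'density' (g/cm^3), 'mu' (1/cm at ``energy_kev``) or
        'hu' (Hounsfield units at ``energy_kev``).
        """
        half = self.extent_cm / 2.0
        step = self.extent_cm / n_pixels
        x = -half + step * (np.arange(n_pixels) + 0.5)
        xx, yy = np.meshgrid(x, x[::-1])  # row 0 at +y
        img = np.zeros((n_pixels, n_pixels))
        for p in self.primitives:
            u, v = _to_ellipse_frame(p, xx, yy)
            mask = u * u + v * v <= 1.0
            if value == "density":
                img[mask] = p.density
            else:
                mat = load_material(p.material)
                img[mask] = mat.mu_over_rho(energy_kev) * p.density
        if value == "hu":
            mu_w = load_material("water").mu(energy_kev)
            img = 1000.0 * (img - mu_w) / mu_w
        return img

    # -- config round trip --------------------------------------------------

    def to_yaml(self, path) -> None:
        prims = []
        for p in self.primitives:
            prims.append({"shape": p.shape,
                          "center": [float(c) for c in p.center],
                          "radii": [float(r) for r in p.radii],
                          "material": p.material,
                          "density": float(p.density),
                          "angle_deg": float(p.angle_deg)})
        doc = {"extent_cm": float(self.extent_cm), "primitives": prims}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "Phantom2D":
        doc = yaml.safe_load(Path(path).read_text())
        prims = tuple(
            Primitive(shape=p["shape"], center=tuple(p["center"]),
                      radii=tuple(p["radii"]), material=p["material"],
                      density=float(p["density"]),
                      angle_deg=float(p.get("angle_deg", 0.0)))
            for p in doc["primitives"])
        return cls(prims, float(doc.get("extent_cm", 50.0)))


def _to_ellipse_frame(p: Primitive, x, y):
    """Map world coordinates into the primitive's unit-circle frame."""
    ang = np.deg2rad(p.angle_deg)
    dx, dy = x - p.center[0], y - p.center[1]
    u = (np.cos(ang) * dx + np.sin(ang) * dy) / p.radii[0]
    v = (-np.sin(ang) * dx + np.cos(ang) * dy) / p.radii[1]
    return u, v


def _ray_ellipse_interval(p: Primitive, origins, dirs):
    """Entry/exit parameters of rays against one primitive (0-length on miss)."""
    ou, ov = _to_ellipse_frame(p, origins[:, 0], origins[:, 1])
    ang = np.deg2rad(p.angle_deg)
    du = (np.cos(ang) * dirs[:, 0] + np.sin(ang) * dirs[:, 1]) / p.radii[0]
    dv = (-np.sin(ang) * dirs[:, 0] + np.cos(ang) * dirs[:, 1]) / p.radii[1]
    a = du * du + dv * dv
    b = ou * du + ov * dv
    c = ou * ou + ov * ov - 1.0
    disc = b * b - a * c
    hit = (disc > 0) & (a > 0)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(hit, (-b - sq) / a, 0.0)
        t2 = np.where(hit, (-b + sq) / a, 0.0)
    return t1, t2


# ---------------------------------------------------------------------------
# Study phantoms
# ---------------------------------------------------------------------------

def make_iq_phantom(densities=IQ_INSERT_DENSITIES, cylinder_radius_cm: float = 20.0,
                    ring_radius_cm: float = 12.0, insert_radius_cm: float = 1.5,
                    tissue_density: float = 1.06) -> Phantom2D:
    """The IQ phantom: a tissue cylinder with seven bone-density inserts.

    The inserts sit on a ring (default radius 12 cm), one every 360/7
    degrees, ordered clockwise by decreasing density with the densest insert
    at 12 o'clock.  The exact layout is a package convention — only the
    insert sizes, densities and the 40-cm cylinder are prescribed by the
    study design — and is configurable here.
    """
    prims = [Primitive("circle", (0.0, 0.0),
                       (cylinder_radius_cm, cylinder_radius_cm),
                       "tissue", tissue_density)]
    for k, rho in enumerate(sorted(densities, reverse=True)):
        ang = np.deg2rad(90.0 - k * 360.0 / len(densities))
        center = (ring_radius_cm * np.cos(ang), ring_radius_cm * np.sin(ang))
        prims.append(Primitive("circle", center,
                               (insert_radius_cm, insert_radius_cm),
                               "bone", rho))
    return Phantom2D(tuple(prims))


def iq_insert_centers(phantom: Phantom2D) -> dict:
    """Map insert density -> center (x, y) for ROI construction."""
    return {p.density: p.center for p in phantom.primitives
            if p.material == "bone"}


def make_torso_phantom(seed: int = 0) -> Phantom2D:
    """A procedural torso slice standing in for a licensed anthropomorphic
    voxel phantom.

    An elliptical soft-tissue body with two low-density lungs, a spine and
    two lateral rib bones, sized so central-channel basis-equivalent
    thicknesses fall in the ~18-32 cm (tissue) and <= ~5 cm (bone) ranges
    typical of an adult torso.  ``seed`` drives a small (+-2%) reproducible
    anatomical jitter.
    """
    rng = np.random.default_rng(seed)

    def jitter():
        return 1.0 + rng.uniform(-0.02, 0.02)

    body = Primitive("ellipse", (0.0, 0.0), (16.0 * jitter(), 11.0 * jitter()),
                     "tissue", 1.06)
    lungs = [Primitive("ellipse", (sx * 5.5 * jitter(), 2.0),
                       (3.0 * jitter(), 4.0 * jitter()), "tissue", 0.26)
             for sx in (-1.0, 1.0)]
    spine = Primitive("circle", (0.0, -6.5 * jitter()), (1.75, 1.75),
                      "bone", 1.60)
    ribs = [Primitive("ellipse", (sx * 13.8, 0.0), (1.0, 2.5 * jitter()),
                      "bone", 1.40)
            for sx in (-1.0, 1.0)]
    return Phantom2D((body, *lungs, spine, *ribs))


# ---------------------------------------------------------------------------
# Thickness profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThicknessProfile:
    """Per-view basis-equivalent thicknesses of the central ray, cm."""

    angles_deg: np.ndarray
    tissue_cm: np.ndarray
    bone_cm: np.ndarray


def basis_thickness_profiles(phantom: Phantom2D, n_views: int = 180,
                             arc_deg: float = 180.0) -> ThicknessProfile:
    """Trace the central detector channel's ray over a view sweep.

    Emulates a noiseless scout acquisition with a single central channel:
    each view's ray passes through the isocenter at the view angle, and the
    chords are converted to basis-equivalent thicknesses.  Used to pick a
    per-scan dose-allocation factor.
    """
    if n_views < 1:
        raise ParameterError("n_views must be >= 1")
    angles = arc_deg * np.arange(n_views) / n_views
    rad = np.deg2rad(angles)
    dirs = np.stack([np.sin(rad), -np.cos(rad)], axis=1)  # view 0: ray down
    origins = np.zeros_like(dirs)
    if not phantom.primitives:
        z = np.zeros(n_views)
        return ThicknessProfile(angles, z, z.copy())
    t_eq, b_eq = phantom.basis_equivalent_thicknesses(origins, dirs)
    return ThicknessProfile(angles, t_eq, b_eq)


# ---------------------------------------------------------------------------
# Voxel phantom import (optional path for externally supplied grids)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelPhantom:
    """A per-pixel (material index, density) grid with square pixels.

    Provided so externally generated voxel phantoms can be dropped in via a
    flat 32-bit float file plus a JSON sidecar (keys: nx, ny, dx_cm,
    materials — list mapping material index to a material name).  Line
    integrals use fixed-step midpoint sampling, which is approximate, unlike
    the exact chords of :class:`Phantom2D`.
    """

    density: np.ndarray        # (ny, nx) g/cm^3
    material_index: np.ndarray  # (ny, nx) int
    materials: tuple           # index -> material name
    dx_cm: float

    @classmethod
    def from_files(cls, raw_path, sidecar_path) -> "VoxelPhantom":
        meta = json.loads(Path(sidecar_path).read_text())
        nx, ny = int(meta["nx"]), int(meta["ny"])
        arr = np.fromfile(raw_path, dtype=np.float32)
        if arr.size != 2 * nx * ny:
            raise ParameterError("voxel file size does not match sidecar")
        dens = arr[:nx * ny].reshape(ny, nx).astype(float)
        midx = arr[nx * ny:].reshape(ny, nx).astype(int)
        return cls(dens, midx, tuple(meta["materials"]), float(meta["dx_cm"]))

    def basis_path_lengths(self, origins, directions, step_cm: float = 0.05):
        o = np.atleast_2d(np.asarray(origins, float))
        d = np.atleast_2d(np.asarray(directions, float))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        ny, nx = self.density.shape
        half_x, half_y = nx * self.dx_cm / 2, ny * self.dx_cm / 2
        reach = float(np.hypot(half_x, half_y))
        ts = np.arange(-reach, reach, step_cm) + step_cm / 2
        a = np.zeros((2, o.shape[0]))
        for k, t in enumerate(ts):
            pts = o + t * d
            ix = np.floor((pts[:, 0] + half_x) / self.dx_cm).astype(int)
            iy = np.floor((half_y - pts[:, 1]) / self.dx_cm).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            rho = np.where(ok, self.density[iy.clip(0, ny - 1),
                                            ix.clip(0, nx - 1)], 0.0)
            midx = np.where(ok, self.material_index[iy.clip(0, ny - 1),
                                                    ix.clip(0, nx - 1)], 0)
            for bi in (0, 1):
                sel = np.array([MATERIAL_BASIS_INDEX.get(m, 0) == bi
                                for m in self.materials])[midx]
                a[bi] += np.where(sel, rho, 0.0) * step_cm
        return a[0], a[1]
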