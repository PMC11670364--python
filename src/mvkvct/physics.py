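"""Shared physics layer for MV-kV dual-energy CT modeling.

Materials, polychromatic spectra, detective efficiency, detector response
models, per-ray signal statistics, and dose normalization.  Everything
downstream (CRLB analysis, CT forward projection, material decomposition)
is built on the detected-signal model

    lambda_i = sum_E I_i(E) exp(-sum_j (mu/rho)_j(E) A_j) eta(E) D(E)

where ``I_i`` is the incident fluence of spectrum i (photons per energy bin
per ray), ``A_j = rho_j t_j`` the basis-material mass thicknesses (g/cm^2),
``eta`` the detective efficiency, and ``D`` the detector response:
``D(E) = E`` (keV) for an energy-integrating detector (EID) and
``D(E) = 1`` for a photon-counting detector (PCD).

Units: energies keV, lengths cm, densities g/cm^3, mass thicknesses g/cm^2,
dose microgray (uGy).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "EnergyRangeError",
    "GridError",
    "Spectrum",
    "Material",
    "DetectorModel",
    "RayComposition",
    "load_material",
    "load_spectrum",
    "build_kv_spectrum",
    "build_detuned_mv_spectrum",
    "detective_efficiency",
    "stopping_fraction",
    "dose_per_ray",
    "allocate_dose",
    "expected_signal",
    "signal_variance",
]

KEV_TO_JOULE = 1.602176634e-16
#: depth in a 40-cm water cylinder at which per-ray dose is scored, cm
DOSE_DEPTH_CM = 20.0
#: tabulated energy range common to the bundled material tables, keV
ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 6000.0

#: efficiency anchors: near-unity through the keV range, 20% at 6 MeV
_ETA_FLAT_BELOW_KEV = 150.0
_ETA_AT_6MEV = 0.20


class ParameterError(ValueError):
    """An argument is outside its physically meaningful range."""


class EnergyRangeError(ValueError):
    """A requested energy falls outside the tabulated 10 keV - 6 MeV range."""


class GridError(ValueError):
    """Mismatched or invalid energy grids / array shapes."""


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A polychromatic ray: photons per energy bin.

    ``fluence[k]`` is the number of photons in the bin centered at
    ``energies[k]`` carried by a single ray (the bin width is already
    integrated out, so energy sums over the spectrum are plain sums).
    """

    energies: np.ndarray  # keV, strictly ascending bin centers
    fluence: np.ndarray   # photons per bin per ray, >= 0
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if e.ndim != 1 or e.shape != f.shape:
            raise GridError("energies and fluence must be matching 1-D arrays")
        if e.size and np.any(np.diff(e) <= 0):
            raise GridError("energies must be strictly increasing")
        if np.any(f < 0):
            raise ParameterError("fluence must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def mean_energy(self) -> float:
        """Fluence-weighted mean energy, keV."""
        tot = self.total_fluence
        if tot <= 0:
            raise ParameterError("mean energy undefined for an empty spectrum")
        return float((self.fluence * self.energies).sum() / tot)

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise ParameterError("scale factor must be non-negative")
        return replace(self, fluence=self.fluence * factor)


def load_spectrum(path, label: str | None = None) -> Spectrum:
    """Read a two-column ``energy_keV fluence`` text file ('#' comments)."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise GridError(f"spectrum file {path} needs two columns")
    return Spectrum(arr[:, 0], arr[:, 1], label or Path(path).stem)


def build_kv_spectrum(kvp: float = 80.0, filtration_mm_al: float = 2.5) -> Spectrum:
    """Analytic diagnostic kV spectrum.

    Kramers-type bremsstrahlung fluence proportional to ``(kvp - E)/E``,
    hardened by ``filtration_mm_al`` of aluminum, on a 1-keV grid from
    10 keV to the tube potential, and normalized so a single ray delivers
    1 uGy to the center of a 40-cm water cylinder.  The analytic shape is a
    stand-in for a measured tube spectrum; measured spectra can be loaded
    with :func:`load_spectrum` instead.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ParameterError(f"kvp={kvp} outside the supported 40-150 kV range")
    if filtration_mm_al < 0:
        raise ParameterError("filtration must be non-negative")
    edges = np.arange(ENERGY_MIN_KEV, kvp + 1e-9, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = (kvp - centers) / centers  # photons per keV, unnormalized
    al = load_material("aluminum")
    atten = np.exp(-al.mu(centers) * 0.1 * filtration_mm_al)
    fluence = np.clip(density * atten, 0.0, None)  # x1 keV bin width
    spec = Spectrum(centers, fluence, label=f"{kvp:g}kVp")
    return spec.scaled(1.0 / dose_per_ray(spec))


def build_detuned_mv_spectrum(e_folding_kev: float = 1000.0,
                              e_max_kev: float = 6000.0) -> Spectrum:
    """Analytic detuned 6-MV treatment-beam spectrum for imaging.

    Fluence proportional to ``E * exp(-E/E0)`` with E0 = 1 MeV, so the mode
    sits at ~1 MeV and the mean energy is ~1.9 MeV (< 3 MeV), truncated at
    6 MeV, on a 20-keV grid; normalized to 1 uGy per ray.  Stands in for a
    softened linac spectrum; a tabulated one can be loaded instead.
    """
    edges = np.arange(20.0, e_max_kev + 1e-9, 20.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = centers * np.exp(-centers / e_folding_kev) * 20.0
    spec = Spectrum(centers, fluence, label="detuned-6MV")
    return spec.scaled(1.0 / dose_per_ray(spec))


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """A material with density and energy-dependent mass coefficients.

    ``mu_over_rho`` / ``muen_over_rho`` interpolate the bundled tables
    log-log between grid points, which keeps both curves positive and
    monotone-safe between samples.
    """

    name: str
    density: float  # g/cm^3
    table_energies: np.ndarray = field(repr=False)  # keV
    table_mu: np.ndarray = field(repr=False)        # cm^2/g
    table_muen: np.ndarray = field(repr=False)      # cm^2/g

    def _interp(self, energy_kev, table):
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.table_energies[0], self.table_energies[-1]
        if np.any(e < lo - 1e-9) or np.any(e > hi + 1e-9):
            raise EnergyRangeError(
                f"{self.name}: energy outside tabulated {lo:g}-{hi:g} keV")
        out = np.exp(np.interp(np.log(e), np.log(self.table_energies),
                               np.log(table)))
        return out if out.shape else float(out)

    def mu_over_rho(self, energy_kev):
        """Mass attenuation coefficient (mu/rho), cm^2/g."""
        return self._interp(energy_kev, self.table_mu)

    def muen_over_rho(self, energy_kev):
        """Mass energy-absorption coefficient (mu_en/rho), cm^2/g."""
        return self._interp(energy_kev, self.table_muen)

    def mu(self, energy_kev):
        """Linear attenuation coefficient at the material density, 1/cm."""
        return self.density * self.mu_over_rho(energy_kev)

    def with_density(self, density: float) -> "Material":
        if density <= 0:
            raise ParameterError("density must be positive")
        return replace(self, density=density)

    @classmethod
    def from_file(cls, path, name: str, density: float) -> "Material":
        """Load a three-column ``energy_keV mu/rho muen/rho`` text table."""
        arr = np.loadtxt(path, comments="#", ndmin=2)
        if arr.shape[1] < 3:
            raise GridError(f"material table {path} needs three columns")
        if np.any(arr[:, 1:] <= 0):
            raise ParameterError(f"material table {path} has non-positive entries")
        return cls(name, density, arr[:, 0], arr[:, 1], arr[:, 2])


#: bundled materials and their default densities (g/cm^3); tissue and bone
#: densities follow the decomposition basis convention.
BUNDLED_MATERIALS = {
    "water": 1.000,
    "tissue": 1.06,
    "bone": 1.85,
    "silicon": 2.33,
    "cdte": 5.85,
    "aluminum": 2.699,
}


@functools.lru_cache(maxsize=None)
def _load_bundled(name: str) -> Material:
    ref = resources.files("mvkvct").joinpath(f"data/{name}.txt")
    with resources.as_file(ref) as path:
        return Material.from_file(path, name, BUNDLED_MATERIALS[name])


def load_material(name: str, density: float | None = None) -> Material:
    """Return a bundled material, optionally at a non-default density."""
    key = name.lower()
    if key not in BUNDLED_MATERIALS:
        raise ParameterError(
            f"unknown material {name!r}; bundled: {sorted(BUNDLED_MATERIALS)}")
    mat = _load_bundled(key)
    return mat if density is None else mat.with_density(density)


def tissue_bone_basis() -> tuple[Material, Material]:
    """The (tissue, bone) decomposition basis pair at rho = 1.06, 1.85."""
    return load_material("tissue"), load_material("bone")


# ---------------------------------------------------------------------------
# Detector models
# ---------------------------------------------------------------------------

def detective_efficiency(energy_kev):
    """Shared detective efficiency eta(E).

    Unity through the diagnostic keV range (up to 150 keV), then declining
    log-linearly in energy to 0.20 at 6 MeV, emulating a high-efficiency
    megavoltage fan-beam detector.  The same curve is used for both detector
    models so that only the photon weighting scheme differs.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
        raise EnergyRangeError("efficiency tabulated for 10 keV - 6 MeV only")
    slope = (_ETA_AT_6MEV - 1.0) / np.log(ENERGY_MAX_KEV / _ETA_FLAT_BELOW_KEV)
    eta = 1.0 + slope * np.log(np.maximum(e, _ETA_FLAT_BELOW_KEV)
                               / _ETA_FLAT_BELOW_KEV)
    eta = np.clip(eta, _ETA_AT_6MEV, 1.0)
    return eta if eta.shape else float(eta)


@dataclass(frozen=True)
class DetectorModel:
    """EID or PCD response model.

    The EID weights each detected photon by its energy (D(E) = E, keV) and
    carries additive electronic noise of standard deviation
    ``electronic_noise_sd`` counts (scaled by the mean beam energy in the
    signal-variance model).  The PCD counts photons with unit weight and a
    low pulse-height threshold that suppresses electronic noise entirely.
    """

    kind: str  # "eid" | "pcd"
    electronic_noise_sd: float = 0.0  # sigma_e, counts
    efficiency: Callable = detective_efficiency

    def __post_init__(self):
        if self.kind not in ("eid", "pcd"):
            raise ParameterError("detector kind must be 'eid' or 'pcd'")
        if self.electronic_noise_sd < 0:
            raise ParameterError("electronic noise sd must be >= 0")
        if self.kind == "pcd" and self.electronic_noise_sd != 0:
            raise ParameterError("the PCD model is electronic-noise free")

    def response(self, energy_kev):
        """Detector response D(E): E (keV) for EID, 1 for PCD."""
        e = np.asarray(energy_kev, dtype=float)
        return e.copy() if self.kind == "eid" else np.ones_like(e)

    @classmethod
    def eid(cls, sigma_e: float = 10.0) -> "DetectorModel":
        return cls("eid", sigma_e)

    @classmethod
    def pcd(cls) -> "DetectorModel":
        return cls("pcd", 0.0)


# ---------------------------------------------------------------------------
# Ray composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RayComposition:
    """Basis-material thicknesses along one line integral."""

    thicknesses: np.ndarray  # t_j, cm
    densities: np.ndarray    # rho_j, g/cm^3

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.thicknesses, dtype=float))
        rho = np.atleast_1d(np.asarray(self.densities, dtype=float))
        if t.shape != rho.shape:
            raise GridError("thicknesses and densities must match in shape")
        if np.any(t < 0):
            raise ParameterError("thicknesses must be non-negative")
        if np.any(rho <= 0):
            raise ParameterError("densities must be positive")
        object.__setattr__(self, "thicknesses", t)
        object.__setattr__(self, "densities", rho)

    @property
    def mass_thicknesses(self) -> np.ndarray:
        """A_j = rho_j * t_j, g/cm^2."""
        return self.thicknesses * self.densities

    @classmethod
    def tissue_bone(cls, t_tissue_cm: float, t_bone_cm: float,
                    densities: Sequence[float] = (1.06, 1.85)) -> "RayComposition":
        return cls(np.array([t_tissue_cm, t_bone_cm]), np.asarray(densities, float))

    @classmethod
    def from_mass_thicknesses(cls, a: Sequence[float],
                              densities: Sequence[float] = (1.06, 1.85)
                              ) -> "RayComposition":
        rho = np.asarray(densities, float)
        return cls(np.asarray(a, float) / rho, rho)


# ---------------------------------------------------------------------------
# Per-ray signal statistics
# ---------------------------------------------------------------------------

def stopping_fraction(material: Material, thickness_cm: float, energy_kev: float):
    """Fraction of photons at ``energy_kev`` stopped by a slab: 1 - exp(-mu t)."""
    if np.any(np.asarray(thickness_cm) < 0):
        raise ParameterError("slab thickness must be non-negative")
    return -np.expm1(-material.mu(energy_kev) * thickness_cm)


def dose_per_ray(spectrum: Spectrum, water: Material | None = None) -> float:
    """Dose delivered by one ray to the center of a 40-cm water cylinder, uGy.

    Primary-beam only: the energy fluence surviving 20 cm of water times the
    water mass energy-absorption coefficient (no scatter buildup).  Linear in
    the spectrum fluence; an empty spectrum gives 0.
    """
    if spectrum.energies.size == 0:
        return 0.0
    water = water if water is not None else load_material("water")
    e = spectrum.energies
    primary = spectrum.fluence * np.exp(-water.mu(e) * DOSE_DEPTH_CM)
    gray = float((primary * water.muen_over_rho(e) * e).sum()) \
        * KEV_TO_JOULE * 1e3  # J/g -> Gy
    return gray * 1e6


def allocate_dose(mv: Spectrum, kv: Spectrum, r: float,
                  total_ugy: float) -> tuple[Spectrum, Spectrum]:
    """Split a fixed per-ray dose between the MV and kV spectra.

    The MV spectrum is rescaled to deliver ``r * total_ugy`` and the kV
    spectrum the remaining ``(1 - r) * total_ugy``.
    """
    if not 0.01 <= r <= 0.99:
        raise ParameterError("allocation fraction r must lie in [0.01, 0.99]")
    if total_ugy <= 0:
        raise ParameterError("total dose must be positive")
    d_mv, d_kv = dose_per_ray(mv), dose_per_ray(kv)
    if d_mv <= 0 or d_kv <= 0:
        raise ParameterError("both spectra must deliver nonzero dose")
    return (mv.scaled(r * total_ugy / d_mv),
            kv.scaled((1.0 - r) * total_ugy / d_kv))


def _detected_weights(spectrum: Spectrum, detector: DetectorModel):
    eta = detector.efficiency(spectrum.energies)
    return spectrum.fluence * eta


def transmission(spectrum: Spectrum, composition: RayComposition,
                 basis: Sequence[Material]) -> np.ndarray:
    """Per-bin transmission exp(-sum_j (mu/rho)_j A_j) on the spectrum grid."""
    if len(basis) != composition.thicknesses.size:
        raise GridError("basis pair and composition must have equal length")
    tau = np.zeros(spectrum.energies.shape)
    for mat, a in zip(basis, composition.mass_thicknesses):
        tau += mat.mu_over_rho(spectrum.energies) * a
    return np.exp(-tau)


def expected_signal(spectrum: Spectrum, composition: RayComposition,
                    basis: Sequence[Material], detector: DetectorModel) -> float:
    """Expected detected signal of one ray.

    Counts for a PCD; count-weighted keV for an EID.
    """
    tau = transmission(spectrum, composition, basis)
    w = _detected_weights(spectrum, detector)
    return float((w * tau * detector.response(spectrum.energies)).sum())


def signal_variance(spectrum: Spectrum, composition: RayComposition,
                    basis: Sequence[Material], detector: DetectorModel) -> float:
    """Variance of the detected signal of one ray.

    PCD: Poisson, variance = expected counts.  EID: Gaussian approximation of
    the compound-Poisson energy-weighted sum, sum I tau eta E^2, plus the
    additive electronic term (sigma_e * Ebar_i)^2 where Ebar_i is the
    fluence-weighted mean energy of the incident spectrum.
    """
    tau = transmission(spectrum, composition, basis)
    w = _detected_weights(spectrum, detector)
    if detector.kind == "pcd":
        return float((w * tau).sum())
    quantum = float((w * tau * spectrum.energies ** 2).sum())
    electronic = (detector.electronic_noise_sd * spectrum.mean_energy()) ** 2
    return quantum + electronic
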