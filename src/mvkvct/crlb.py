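"""Cramer-Rao lower-bound analysis of two-material, two-spectrum line integrals.

For one polychromatic ray through tissue and bone mass thicknesses
``A = (A_tissue, A_bone)`` measured with an MV and a kV spectrum, the
Fisher information of a Gaussian fixed-variance likelihood is

    F_jk = sum_i (1 / v_i) (d lambda_i / d A_j) (d lambda_i / d A_k)

with the signal means ``lambda_i`` and variances ``v_i`` from
:mod:`mvkvct.physics`.  The CRLB on an unbiased mass-thickness estimate is
``sigma_Aj^2 = (F^-1)_jj`` and the basis-material signal-to-noise ratio is
the unitless ``SNR_j = A_j / sigma_Aj`` — an upper bound on achievable image
quality that lets detector weighting schemes (EID vs PCD) be compared
independently of any particular estimator.

The module also sweeps the MV/kV dose-allocation fraction r (the MV spectrum
delivers ``r`` of a fixed per-ray dose, the kV spectrum ``1 - r``) and maps
dose-optimized SNR over grids of tissue/bone thickness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .physics import (
    DetectorModel,
    Material,
    ParameterError,
    RayComposition,
    Spectrum,
    allocate_dose,
    dose_per_ray,
    signal_variance,
    transmission,
)

__all__ = [
    "SingularFisherError",
    "FisherMatrix",
    "SnrResult",
    "SnrSurface",
    "fisher_matrix",
    "crlb_variance",
    "basis_snr",
    "optimize_allocation",
    "snr_surface",
    "percent_improvement",
    "default_r_grid",
    "surface_to_frame",
]

_DEFAULT_DOSE_UGY = 1.0  # per-ray dose of the single-ray study


class SingularFisherError(np.linalg.LinAlgError):
    """The Fisher matrix carries no independent material information."""


@dataclass(frozen=True)
class FisherMatrix:
    """2x2 symmetric Fisher information in (g/cm^2)^-2, order (tissue, bone)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ParameterError("Fisher matrix must be 2x2")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))  # enforce symmetry

    @property
    def determinant(self) -> float:
        m = self.matrix
        return float(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0])


@dataclass(frozen=True)
class SnrResult:
    """Per-basis-material SNR and CRLB at one dose allocation."""

    snr: np.ndarray   # A_j / sigma_Aj, order (tissue, bone)
    crlb: np.ndarray  # sigma_Aj^2, (g/cm^2)^2
    r: float          # MV dose-allocation fraction used


def _signal_gradient(spectrum: Spectrum, composition: RayComposition,
                     basis: Sequence[Material], detector: DetectorModel
                     ) -> np.ndarray:
    """d lambda / d A_j = -sum I tau (mu/rho)_j eta D, per basis material."""
    e = spectrum.energies
    tau = transmission(spectrum, composition, basis)
    core = spectrum.fluence * tau * detector.efficiency(e) * detector.response(e)
    return np.array([-(core * mat.mu_over_rho(e)).sum() for mat in basis])


def fisher_matrix(spectra: Sequence[Spectrum], composition: RayComposition,
                  basis: Sequence[Material], detector: DetectorModel
                  ) -> FisherMatrix:
    """Fisher information accumulated over the (MV, kV) spectrum pair."""
    f = np.zeros((2, 2))
    for spec in spectra:
        grad = _signal_gradient(spec, composition, basis, detector)
        v = signal_variance(spec, composition, basis, detector)
        if v > 0:
            f += np.outer(grad, grad) / v
    return FisherMatrix(f)


def crlb_variance(fisher: FisherMatrix) -> np.ndarray:
    """CRLB variances (F^-1)_jj for each basis material.

    Raises :class:`SingularFisherError` when the spectra carry no independent
    material information (infinite CRLB).
    """
    m = fisher.matrix
    det = fisher.determinant
    scale = m[0, 0] * m[1, 1]
    if det <= 0 or (scale > 0 and det < 1e-14 * scale):
        raise SingularFisherError("Fisher matrix is singular; CRLB is infinite")
    return np.array([m[1, 1], m[0, 0]]) / det


def basis_snr(spectra: Sequence[Spectrum], composition: RayComposition,
              basis: Sequence[Material], detector: DetectorModel,
              r: float, total_dose_ugy: float = _DEFAULT_DOSE_UGY) -> SnrResult:
    """Basis-material SNR at MV dose fraction ``r`` and fixed per-ray dose."""
    mv, kv = allocate_dose(spectra[0], spectra[1], r, total_dose_ugy)
    crlb = crlb_variance(fisher_matrix((mv, kv), composition, basis, detector))
    snr = composition.mass_thicknesses / np.sqrt(crlb)
    return SnrResult(snr=snr, crlb=crlb, r=r)


def default_r_grid() -> np.ndarray:
    """The dose-allocation sweep: r = 0.01 ... 0.99 in steps of 0.01."""
    return np.round(np.arange(1, 100) * 0.01, 2)


# ---------------------------------------------------------------------------
# Fast dose-allocation sweeps
#
# Rescaling a spectrum by s multiplies its signal gradient by s and its
# quantum variance by s while the electronic variance stays fixed, so a
# single set of unit-dose ray moments supports the whole r sweep.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _RayMoments:
    grad: np.ndarray        # d lambda / dA at unit (1 uGy) spectrum scale
    quantum_var: float      # variance per unit scale
    electronic_var: float   # additive variance, scale-independent


def _unit_dose(spectrum: Spectrum) -> Spectrum:
    return spectrum.scaled(1.0 / dose_per_ray(spectrum))


def _ray_moments(spectrum: Spectrum, composition: RayComposition,
                 basis: Sequence[Material], detector: DetectorModel
                 ) -> _RayMoments:
    unit = _unit_dose(spectrum)
    grad = _signal_gradient(unit, composition, basis, detector)
    e = unit.energies
    tau = transmission(unit, composition, basis)
    w = unit.fluence * tau * detector.efficiency(e)
    if detector.kind == "pcd":
        quantum, electronic = float(w.sum()), 0.0
    else:
        quantum = float((w * e ** 2).sum())
        electronic = (detector.electronic_noise_sd * unit.mean_energy()) ** 2
    return _RayMoments(grad, quantum, electronic)


def _snr_over_r(moments: Sequence[_RayMoments], a: np.ndarray,
                r_grid: np.ndarray, total_dose_ugy: float) -> np.ndarray:
    """SNR_j on the r grid, shape (n_r, 2); singular cells become 0."""
    scales = np.stack([r_grid * total_dose_ugy,
                       (1.0 - r_grid) * total_dose_ugy])  # (2 spectra, n_r)
    f = np.zeros((r_grid.size, 2, 2))
    for mom, s in zip(moments, scales):
        v = s * mom.quantum_var + mom.electronic_var
        f += (s ** 2 / v)[:, None, None] * np.outer(mom.grad, mom.grad)
    det = f[:, 0, 0] * f[:, 1, 1] - f[:, 0, 1] * f[:, 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        crlb = np.stack([f[:, 1, 1], f[:, 0, 0]], axis=1) / det[:, None]
        snr = np.where(crlb > 0, a[None, :] / np.sqrt(crlb), 0.0)
    return snr


def optimize_allocation(spectra: Sequence[Spectrum], composition: RayComposition,
                        basis: Sequence[Material], detector: DetectorModel,
                        total_dose_ugy: float = _DEFAULT_DOSE_UGY,
                        r_grid: np.ndarray | None = None
                        ) -> tuple[np.ndarray, SnrResult]:
    """Maximize SNR_j over the dose-allocation grid, per basis material.

    Returns ``(r_opt, best)`` where ``r_opt[j]`` is the grid point maximizing
    material j's SNR (ties broken toward smaller r) and ``best`` holds the
    corresponding per-material optima (``best.r`` is the bone optimum).
    """
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, float)
    if r_grid.size == 0:
        raise ParameterError("r grid must be non-empty")
    if np.any(r_grid < 0.01) or np.any(r_grid > 0.99):
        raise ParameterError("r grid must lie within [0.01, 0.99]")
    moments = [_ray_moments(s, composition, basis, detector) for s in spectra]
    snr = _snr_over_r(moments, composition.mass_thicknesses, r_grid,
                      total_dose_ugy)
    idx = np.argmax(snr, axis=0)  # first occurrence -> smaller r on ties
    r_opt = r_grid[idx]
    best_snr = snr[idx, [0, 1]]
    crlb = np.where(best_snr > 0,
                    (composition.mass_thicknesses / np.maximum(best_snr, 1e-300)) ** 2,
                    np.inf)
    return r_opt, SnrResult(snr=best_snr, crlb=crlb, r=float(r_opt[1]))


@dataclass(frozen=True)
class SnrSurface:
    """Dose-optimized SNR over a (tissue, bone) thickness grid."""

    tissue_cm: np.ndarray   # (nt,)
    bone_cm: np.ndarray     # (nb,)
    snr: np.ndarray         # (2, nt, nb), order (tissue, bone) material
    r_opt: np.ndarray       # (2, nt, nb)
    detector_kind: str


def snr_surface(tissue_cm: np.ndarray, bone_cm: np.ndarray,
                basis: Sequence[Material], detector: DetectorModel,
                spectra: Sequence[Spectrum],
                total_dose_ugy: float = _DEFAULT_DOSE_UGY,
                r_grid: np.ndarray | None = None,
                densities: Sequence[float] = (1.06, 1.85)) -> SnrSurface:
    """Dose-optimized SNR for every thickness pair on the grid."""
    tissue_cm = np.asarray(tissue_cm, float)
    bone_cm = np.asarray(bone_cm, float)
    snr = np.zeros((2, tissue_cm.size, bone_cm.size))
    ropt = np.zeros_like(snr)
    for i, t1 in enumerate(tissue_cm):
        for j, t2 in enumerate(bone_cm):
            comp = RayComposition.tissue_bone(t1, t2, densities)
            r, best = optimize_allocation(spectra, comp, basis, detector,
                                          total_dose_ugy, r_grid)
            snr[:, i, j] = best.snr
            ropt[:, i, j] = r
    return SnrSurface(tissue_cm, bone_cm, snr, ropt, detector.kind)


def percent_improvement(pcd: SnrSurface, eid: SnrSurface) -> np.ndarray:
    """PCD-over-EID percent SNR difference, shape (2, nt, nb)."""
    if pcd.snr.shape != eid.snr.shape:
        raise ParameterError("surfaces must share the same thickness grid")
    return 100.0 * (pcd.snr - eid.snr) / eid.snr


def surface_to_frame(surface: SnrSurface) -> pd.DataFrame:
    """Flatten a surface to the CSV export layout."""
    t, b = np.meshgrid(surface.tissue_cm, surface.bone_cm, indexing="ij")
    return pd.DataFrame({
        "t_tissue_cm": t.ravel(),
        "t_bone_cm": b.ravel(),
        "snr_tissue": surface.snr[0].ravel(),
        "snr_bone": surface.snr[1].ravel(),
        "r_opt_tissue": surface.r_opt[0].ravel(),
        "r_opt_bone": surface.r_opt[1].ravel(),
        "detector": surface.detector_kind,
    })
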