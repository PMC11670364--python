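"""Sinogram-domain two-material decomposition of MV/kV measurement pairs.

Each detector pixel provides two log-transmission measurements

    L_i = ln(air_i / measured_i),    i in {MV, kV}

and the polychromatic model predicts

    M_i(A) = ln(lambda_i(0) / lambda_i(A)),

with ``lambda_i`` the expected detected signal at basis mass thicknesses
``A = (A_tissue, A_bone)``.  The decomposition solves the exactly
determined 2x2 nonlinear system ``M(A) = L`` per pixel by Gauss-Newton
iteration with step halving, started from a closed-form solve that uses
fluence-weighted effective attenuation coefficients.  Negative estimates
are permitted — noise can legitimately push mass thicknesses below zero,
and clamping would bias the estimator.

All pixels are iterated simultaneously (vectorized over the sinogram),
which keeps the per-iteration cost at one transmission evaluation per
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward import Sinogram, _bin_weights, _mu_matrix
from .physics import DetectorModel, GridError, Material, Spectrum

__all__ = [
    "SignalError",
    "DecompositionResult",
    "decompose_ray",
    "decompose_sinogram",
]

log = logging.getLogger(__name__)

MAX_ITERATIONS = 50
#: converged when the update falls below this, g/cm^2
STEP_TOLERANCE = 1e-8
#: ... or the residual norm below this
RESIDUAL_TOLERANCE = 1e-10
_MAX_HALVINGS = 10
_PIXEL_CHUNK = 16384


class SignalError(ValueError):
    """A measured or air signal is non-positive."""


@dataclass
class DecompositionResult:
    """Basis mass-thickness sinograms plus convergence bookkeeping."""

    a_tissue: np.ndarray   # g/cm^2
    a_bone: np.ndarray     # g/cm^2
    iterations: np.ndarray
    converged: np.ndarray  # bool

    @property
    def n_unconverged(self) -> int:
        return int((~self.converged).sum())


@dataclass(frozen=True)
class _SpectrumModel:
    """Pre-reduced per-spectrum quantities for the forward model."""

    weights: np.ndarray     # I(E) eta(E) D(E) per bin
    mu: np.ndarray          # (n_bins, 2) basis mass attenuation
    log_air: float
    effective_mu: np.ndarray  # weight-averaged (mu/rho)_j, for the init

    @classmethod
    def build(cls, spectrum: Spectrum, basis: Sequence[Material],
              detector: DetectorModel) -> "_SpectrumModel":
        w = _bin_weights(spectrum, detector) * detector.response(spectrum.energies)
        mu = _mu_matrix(spectrum, basis)
        total = w.sum()
        return cls(w, mu, float(np.log(total)), (w @ mu) / total)

    def log_signal_and_jac(self, a: np.ndarray):
        """ln lambda(A) and d(-ln lambda)/dA for A of shape (n, 2)."""
        tau = np.exp(-(a @ self.mu.T))          # (n, n_bins)
        lam = tau @ self.weights
        jac = (tau * self.weights) @ self.mu / lam[:, None]
        return np.log(lam), jac


def _gauss_newton(l_meas: np.ndarray, models: Sequence[_SpectrumModel]):
    """Solve M(A) = L for all pixels at once.

    ``l_meas`` has shape (2, n): log-transmission per spectrum and pixel.
    Returns (a, iterations, converged).
    """
    n = l_meas.shape[1]
    # closed-form init with effective attenuation coefficients
    m_eff = np.stack([m.effective_mu for m in models])  # (2, 2)
    a = np.linalg.solve(m_eff, l_meas).T                # (n, 2)

    def residual(a_arr, cols):
        """Residual and Jacobian at ``a_arr`` for the pixels in ``cols``."""
        res = np.empty((2, a_arr.shape[0]))
        jacs = []
        for i, m in enumerate(models):
            log_lam, jac = m.log_signal_and_jac(a_arr)
            res[i] = l_meas[i, cols] - (m.log_air - log_lam)
            jacs.append(jac)
        return res, jacs

    res, jacs = residual(a, slice(None))
    ssr = (res ** 2).sum(axis=0)
    iters = np.zeros(n, dtype=int)
    converged = ssr < RESIDUAL_TOLERANCE ** 2
    active = ~converged
    for it in range(MAX_ITERATIONS):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        # model Jacobian dM_i/dA_j = jac rows (M = log_air - log lambda,
        # and log_signal_and_jac returns d(-ln lambda)/dA directly)
        j = np.stack([jacs[0][idx], jacs[1][idx]], axis=1)  # (m, 2, 2)
        det = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        r = res[:, idx]
        step = np.empty((idx.size, 2))
        step[:, 0] = (j[:, 1, 1] * r[0] - j[:, 0, 1] * r[1]) / det
        step[:, 1] = (-j[:, 1, 0] * r[0] + j[:, 0, 0] * r[1]) / det
        step = np.nan_to_num(step)

        # step halving: accept the first scale that does not increase ssr
        scale = np.ones(idx.size)
        base_ssr = ssr[idx]
        a_new = a[idx] + step
        res_new, _ = residual(a_new, idx)
        ssr_new = (res_new ** 2).sum(axis=0)
        for _ in range(_MAX_HALVINGS):
            worse = ssr_new > base_ssr * (1 + 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
            a_new[worse] = a[idx[worse]] + scale[worse, None] * step[worse]
            res_w, _ = residual(a_new[worse], idx[worse])
            ssr_new[worse] = (res_w ** 2).sum(axis=0)
        a[idx] = a_new
        iters[idx] += 1

        res_act, jacs_act = residual(a[idx], idx)
        res[:, idx] = res_act
        ssr[idx] = (res_act ** 2).sum(axis=0)
        for i in range(2):
            jacs[i][idx] = jacs_act[i]
        done = (np.abs(scale[:, None] * step).max(axis=1) < STEP_TOLERANCE) \
            | (ssr[idx] < RESIDUAL_TOLERANCE ** 2)
        converged[idx] |= done
        active[idx[done]] = False
    return a, iters, converged


def _check_positive(name, arr):
    if np.any(np.asarray(arr) <= 0):
        raise SignalError(f"{name} must be positive (clamp noisy data first)")


def decompose_ray(measured: Sequence[float], air: Sequence[float],
                  spectra: Sequence[Spectrum], basis: Sequence[Material],
                  detector: DetectorModel) -> tuple[float, float]:
    """Decompose one (MV, kV) signal pair into (A_tissue, A_bone), g/cm^2."""
    measured = np.asarray(measured, float)
    air = np.asarray(air, float)
    _check_positive("measured signals", measured)
    _check_positive("air references", air)
    models = [_SpectrumModel.build(s, basis, detector) for s in spectra]
    l_meas = np.log(air / measured)[:, None]
    a, _, converged = _gauss_newton(l_meas, models)
    if not converged[0]:
        log.warning("decompose_ray did not converge in %d iterations",
                    MAX_ITERATIONS)
    return float(a[0, 0]), float(a[0, 1])


def decompose_sinogram(mv_sino: Sinogram, kv_sino: Sinogram,
                       air: Sequence[float], spectra: Sequence[Spectrum],
                       basis: Sequence[Material], detector: DetectorModel
                       ) -> DecompositionResult:
    """Per-pixel Gauss-Newton decomposition of an MV/kV sinogram pair."""
    if mv_sino.values.shape != kv_sino.values.shape:
        raise GridError("MV and kV sinograms must have matching shapes")
    _check_positive("air references", air)
    _check_positive("MV sinogram", mv_sino.values)
    _check_positive("kV sinogram", kv_sino.values)
    shape = mv_sino.values.shape
    l_meas = np.stack([np.log(air[0] / mv_sino.values.ravel()),
                       np.log(air[1] / kv_sino.values.ravel())])
    models = [_SpectrumModel.build(s, basis, detector) for s in spectra]
    n = l_meas.shape[1]
    a = np.empty((n, 2))
    iters = np.empty(n, dtype=int)
    conv = np.empty(n, dtype=bool)
    for lo in range(0, n, _PIXEL_CHUNK):
        sl = slice(lo, lo + _PIXEL_CHUNK)
        a[sl], iters[sl], conv[sl] = _gauss_newton(l_meas[:, sl], models)
    result = DecompositionResult(a[:, 0].reshape(shape), a[:, 1].reshape(shape),
                                 iters.reshape(shape), conv.reshape(shape))
    log.info("decomposed %d pixels: %d unconverged, max %d iterations",
             n, result.n_unconverged, int(iters.max(initial=0)))
    return result
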