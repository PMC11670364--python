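"""Fan-beam FBP reconstruction, virtual monoenergetic imaging, and
image-quality analysis.

Basis mass-thickness sinograms (g/cm^2) are reconstructed with equiangular
fan-beam filtered back-projection — cosine pre-weighting, a frequency-domain
ramp filter hard-cut at 80% of the channel Nyquist frequency (no apodization
window), and 1/L^2 distance-weighted backprojection over the full rotation —
yielding basis density images in g/cm^3.  Virtual monoenergetic images
(VMIs) combine the two basis images pixelwise,

    VMI(E0) = rho_tissue (mu/rho)_tissue(E0) + rho_bone (mu/rho)_bone(E0),

in 1/cm, convertible to Hounsfield units against water at the same energy.
Contrast-to-noise ratio is |mean(insert) - mean(background)| / std(background)
over disjoint ROI masks, and noise maps are per-pixel sample standard
deviations over repeated noisy acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .forward import FanBeamGeometry, Sinogram
from .physics import Material, ParameterError, load_material

__all__ = [
    "ReconImage",
    "RoiMask",
    "fbp_reconstruct",
    "synthesize_vmi",
    "to_hu",
    "measure_cnr",
    "noise_map",
    "disk_roi",
    "background_annulus_roi",
    "save_image",
    "export_png",
]

#: ramp-filter cutoff as a fraction of the channel Nyquist frequency
RAMP_CUTOFF_FRACTION = 0.8
#: VMI synthesis energy range, keV
VMI_ENERGY_RANGE = (20.0, 120.0)


@dataclass
class ReconImage:
    """A square reconstructed image with physical scaling metadata."""

    pixels: np.ndarray
    fov_cm: float = 50.0
    units: str = "g/cm^3"      # "g/cm^3" | "1/cm" | "HU"
    energy_kev: float | None = None

    def __post_init__(self):
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ParameterError("ReconImage requires a square pixel array")

    @property
    def pixel_size_cm(self) -> float:
        return self.fov_cm / self.pixels.shape[0]


@dataclass(frozen=True)
class RoiMask:
    """A boolean region-of-interest mask with a label."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.mask.dtype != bool:
            raise ParameterError("ROI mask must be boolean")
        if not self.mask.any():
            raise ParameterError("ROI mask is empty")


# ---------------------------------------------------------------------------
# Filtered backprojection
# ---------------------------------------------------------------------------

def _equiangular_kernel(n_channels: int, dgamma: float) -> np.ndarray:
    """Spatial ramp kernel for equiangular fan geometry.

    The parallel-beam Ram-Lak kernel with the standard (gamma / sin gamma)^2
    fan correction folded in; support 2*n_channels - 1 taps.
    """
    n = np.arange(-(n_channels - 1), n_channels)
    g = np.zeros(n.size)
    g[n == 0] = 1.0 / (8.0 * dgamma ** 2)
    odd = n % 2 != 0
    g[odd] = -0.5 / (np.pi * np.sin(n[odd] * dgamma)) ** 2
    return g


def fbp_reconstruct(sinogram: Sinogram | np.ndarray,
                    geometry: FanBeamGeometry | None = None,
                    n_pixels: int = 512, fov_cm: float = 50.0) -> ReconImage:
    """Equiangular fan-beam FBP of a line-integral sinogram.

    The sinogram must be in line-integral units (e.g. basis mass thickness,
    g/cm^2); the output is then the corresponding volumetric quantity
    (g/cm^3).  Reconstruction is linear in the sinogram.
    """
    if isinstance(sinogram, Sinogram):
        if geometry is not None and geometry != sinogram.geometry:
            raise ParameterError("geometry argument conflicts with sinogram")
        geometry = sinogram.geometry
        data = sinogram.values
    else:
        if geometry is None:
            raise ParameterError("geometry required for a bare array")
        data = np.asarray(sinogram, float)
    v, c = geometry.n_views, geometry.n_channels
    if data.shape != (v, c):
        raise ParameterError("sinogram shape does not match geometry")

    gamma = np.deg2rad(geometry.channel_angles_deg)
    dgamma = np.deg2rad(geometry.fan_angle_deg) / c
    sid = geometry.source_to_isocenter

    # cosine pre-weighting, then row filtering in the frequency domain
    pre = data * (sid * np.cos(gamma))[None, :]
    kernel = _equiangular_kernel(c, dgamma)
    nfft = int(2 ** np.ceil(np.log2(2 * c)))
    kf = np.fft.rfft(np.roll(np.pad(kernel, (0, nfft - kernel.size)),
                             -(c - 1)))
    freqs = np.fft.rfftfreq(nfft, d=dgamma)
    kf = kf * (freqs <= RAMP_CUTOFF_FRACTION * 0.5 / dgamma)
    q = np.fft.irfft(np.fft.rfft(pre, nfft, axis=1) * kf[None, :],
                     nfft, axis=1)[:, :c] * dgamma

    # distance-weighted backprojection
    half = fov_cm / 2.0
    step = fov_cm / n_pixels
    xs = -half + step * (np.arange(n_pixels) + 0.5)
    xx, yy = np.meshgrid(xs, xs[::-1])  # row 0 at +y
    img = np.zeros(xx.shape)
    beta = np.deg2rad(geometry.view_angles_deg)
    dbeta = np.deg2rad(geometry.arc_deg) / v
    sources = geometry.source_positions()
    for i in range(v):
        sx, sy = sources[i]
        ux, uy = xx - sx, yy - sy
        # central direction and the in-fan normal matching the forward
        # channel-angle sign convention (angles measured clockwise from +y)
        cx, cy = -sx / sid, -sy / sid
        px, py = cy, -cx
        along = ux * cx + uy * cy
        perp = ux * px + uy * py
        gamma_p = np.arctan2(perp, along)
        l2 = ux * ux + uy * uy
        img += np.interp(gamma_p, gamma, q[i], left=0.0, right=0.0) / l2
    img *= dbeta
    return ReconImage(img, fov_cm=fov_cm, units="g/cm^3")


# ---------------------------------------------------------------------------
# VMI synthesis and HU conversion
# ---------------------------------------------------------------------------

def synthesize_vmi(rho_tissue: ReconImage, rho_bone: ReconImage,
                   energy_kev: float,
                   basis: tuple[Material, Material] | None = None) -> ReconImage:
    """Virtual monoenergetic image at ``energy_kev``, in 1/cm."""
    lo, hi = VMI_ENERGY_RANGE
    if not lo <= energy_kev <= hi:
        raise ParameterError(f"VMI energy must lie in {lo:g}-{hi:g} keV")
    if rho_tissue.pixels.shape != rho_bone.pixels.shape:
        raise ParameterError("basis images must have matching shapes")
    if basis is None:
        basis = (load_material("tissue"), load_material("bone"))
    w = [m.mu_over_rho(energy_kev) for m in basis]
    pixels = rho_tissue.pixels * w[0] + rho_bone.pixels * w[1]
    return ReconImage(pixels, fov_cm=rho_tissue.fov_cm, units="1/cm",
                      energy_kev=energy_kev)


def to_hu(vmi: ReconImage, energy_kev: float | None = None,
          water: Material | None = None) -> ReconImage:
    """Convert a linear-attenuation image to Hounsfield units.

    HU = 1000 (mu - mu_water(E0)) / mu_water(E0).
    """
    e0 = energy_kev if energy_kev is not None else vmi.energy_kev
    if e0 is None:
        raise ParameterError("HU conversion needs the VMI energy")
    water = water if water is not None else load_material("water")
    mu_w = water.mu(e0)
    return ReconImage(1000.0 * (vmi.pixels - mu_w) / mu_w,
                      fov_cm=vmi.fov_cm, units="HU", energy_kev=e0)


# ---------------------------------------------------------------------------
# ROI analysis
# ---------------------------------------------------------------------------

def _pixel_grid(n: int, fov_cm: float):
    half = fov_cm / 2.0
    step = fov_cm / n
    xs = -half + step * (np.arange(n) + 0.5)
    return np.meshgrid(xs, xs[::-1])


def disk_roi(center_cm, radius_cm: float, n_pixels: int, fov_cm: float = 50.0,
             erode_px: int = 2, label: str = "") -> RoiMask:
    """A disk ROI eroded ``erode_px`` pixels inside its boundary."""
    xx, yy = _pixel_grid(n_pixels, fov_cm)
    mask = (xx - center_cm[0]) ** 2 + (yy - center_cm[1]) ** 2 <= radius_cm ** 2
    if erode_px > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_px)
    return RoiMask(mask, label)


def background_annulus_roi(insert_centers, insert_radius_cm: float,
                           ring_radius_cm: float, n_pixels: int,
                           fov_cm: float = 50.0, target_area_px: int | None = None,
                           margin_px: int = 4) -> RoiMask:
    """Tissue-background annulus at the insert ring radius.

    A thin annulus centered on the insert ring, with every insert (dilated
    by ``margin_px``) excluded, grown in radial width until it holds at
    least ``target_area_px`` pixels (defaults to the area of one insert ROI).
    """
    xx, yy = _pixel_grid(n_pixels, fov_cm)
    rr = np.hypot(xx, yy)
    px_cm = fov_cm / n_pixels
    excl = np.zeros_like(rr, dtype=bool)
    for c in insert_centers:
        excl |= (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= insert_radius_cm ** 2
    excl = ndimage.binary_dilation(excl, iterations=margin_px)
    if target_area_px is None:
        target_area_px = int(np.pi * (insert_radius_cm / px_cm - 2) ** 2)
    for half_width in np.arange(0.2, ring_radius_cm, 0.1):
        mask = (np.abs(rr - ring_radius_cm) <= half_width) & ~excl
        if mask.sum() >= target_area_px:
            return RoiMask(mask, "background")
    raise ParameterError("could not build a background annulus of the "
                         "requested area")


def measure_cnr(image: ReconImage, insert: RoiMask, background: RoiMask
                ) -> float:
    """CNR = |mean(insert) - mean(background)| / std(background)."""
    if (insert.mask & background.mask).any():
        raise ParameterError("insert and background ROIs must be disjoint")
    bg = image.pixels[background.mask]
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ParameterError("background ROI has zero standard deviation; "
                             "CNR is undefined")
    return float(abs(image.pixels[insert.mask].mean() - bg.mean()) / sd)


def noise_map(realizations) -> ReconImage:
    """Per-pixel sample standard deviation (ddof=1) over noisy realizations."""
    if len(realizations) < 2:
        raise ParameterError("noise map needs at least two realizations")
    first = realizations[0]
    stack = np.stack([r.pixels for r in realizations])
    if any(r.pixels.shape != first.pixels.shape for r in realizations):
        raise ParameterError("realizations must have matching shapes")
    return ReconImage(stack.std(axis=0, ddof=1), fov_cm=first.fov_cm,
                      units=first.units, energy_kev=first.energy_kev)


# ---------------------------------------------------------------------------
# Persistence / export
# ---------------------------------------------------------------------------

def save_image(image: ReconImage, basename) -> None:
    """Write ``<basename>.f32`` (row-major float32) + ``<basename>.json``."""
    import json
    from pathlib import Path
    base = Path(basename)
    image.pixels.astype(np.float32).tofile(base.with_suffix(".f32"))
    meta = {"n": image.pixels.shape[0], "fov_cm": image.fov_cm,
            "units": image.units, "energy_kev": image.energy_kev}
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def export_png(image: ReconImage, path, window_level: float = 0.0,
               window_width: float = 1000.0) -> None:
    """8-bit PNG export with a display window (level/width)."""
    import imageio.v3 as iio
    lo = window_level - window_width / 2.0
    scaled = np.clip((image.pixels - lo) / window_width, 0.0, 1.0)
    iio.imwrite(path, (scaled * 255).astype(np.uint8))
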