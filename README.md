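# mvkvct

Simulation and estimation-theory toolkit for **MV-kV dual-energy CT**:
comparing energy-integrating detectors (EIDs) with non-spectral
photon-counting detectors (PCDs) when a detuned megavoltage treatment beam
and a diagnostic 80-kVp beam image the same object.

Radiotherapy systems already carry an MV source (for treatment, detunable
for imaging) and a kV source (for on-board imaging). Acquiring both
simultaneously enables single-shot dual-energy CT — basis-material
decomposition and virtual monoenergetic images (VMIs) — but the MV channel
is noisy: an EID weights each detected photon by its energy, so a 3-MeV
photon counts 100x more than a far more contrast-informative 30-keV photon,
and EID electronic noise bites hard at the low MV flux that an acceptable
imaging dose allows. A non-spectral PCD weights every photon equally and
thresholds electronic noise away. This package quantifies how much image
quality that buys, at matched dose and matched detective efficiency.

## What it computes

**Single-ray estimation theory.** For one polychromatic ray through tissue
and bone mass thicknesses `A_j = rho_j t_j`, the detected mean is

    lambda_i = ∫ I_i(E) exp(-sum_j (mu/rho)_j(E) A_j) eta(E) D(E) dE

with detector response `D(E) = E` (EID) or `D(E) = 1` (PCD). A Gaussian
fixed-variance likelihood gives the Fisher matrix

    F_jk = sum_i (1/v_i) (d lambda_i / d A_j)(d lambda_i / d A_k),

the Cramér–Rao bound `sigma_Aj^2 = (F^-1)_jj`, and the basis-material
signal-to-noise ratio `SNR_j = A_j / sigma_Aj` — an estimator-independent
ceiling on image quality. The EID variance model is
`∫ I tau eta E^2 dE + (sigma_e Ebar)^2` with `sigma_e = 10` counts; the PCD
is purely Poisson. A fixed per-ray dose (1 µGy to the center of a 40-cm
water cylinder) is split between the beams by an allocation fraction `r`
(MV) / `1-r` (kV), swept 0.01–0.99 to find dose-optimized SNR.

**CT simulation.** An equiangular fan-beam system (55/100 cm, 800 channels,
50° fan, 1200 views over 360°) images procedural phantoms (a 40-cm tissue
cylinder with seven bone inserts of density 1.0–2.2 g/cm³, or a synthetic
torso slice); exact polychromatic forward projection, per-energy-bin Poisson
noise, sinogram-domain Gauss–Newton two-material decomposition, fan-beam FBP
(ramp filter cut at 80% of Nyquist, 512² over a 50-cm FOV), VMI synthesis
`VMI(E0) = rho_1 (mu/rho)_1(E0) + rho_2 (mu/rho)_2(E0)`, HU conversion, CNR
`|m_insert - m_bg| / sigma_bg`, and multi-realization noise maps.

Spectra and the shared detective efficiency `eta(E)` (unity at diagnostic
energies, 0.20 at 6 MeV) are analytic models reproducing the stated beam
properties; measured spectra can be dropped in as two-column
`energy_keV fluence` text files.

## Worked example

```python
import numpy as np
from mvkvct import (build_detuned_mv_spectrum, build_kv_spectrum,
                    tissue_bone_basis, RayComposition, DetectorModel,
                    optimize_allocation)

mv, kv = build_detuned_mv_spectrum(), build_kv_spectrum()
basis = tissue_bone_basis()
ray = RayComposition.tissue_bone(t_tissue_cm=40.0, t_bone_cm=2.0)

for det in (DetectorModel.pcd(), DetectorModel.eid()):
    r_opt, best = optimize_allocation((mv, kv), ray, basis, det)
    print(f"{det.kind}: r_opt (tissue, bone) = {r_opt}, "
          f"SNR (tissue, bone) = {np.round(best.snr, 2)}")
```

prints

```
pcd: r_opt (tissue, bone) = [0.83 0.75], SNR (tissue, bone) = [75.83  9.26]
eid: r_opt (tissue, bone) = [0.85 0.79], SNR (tissue, bone) = [58.13  7.1 ]
```

For a 40-cm tissue path with 2 cm of bone at 1 µGy per ray, both detectors
want most of the dose on the MV beam (it penetrates far better), the PCD
optimum sits at slightly less MV dose than the EID's, and the PCD's
equal-weighting of photons buys ~30% higher SNR for both basis materials at
identical dose and efficiency.

The same studies are available from the shell:

```sh
mvkvct single-ray --outdir out/          # SNR surfaces + r_opt tables (CSV)
mvkvct ct --phantom iq --mv-fraction 0.85 --dose-mgy 10 --outdir out-ct/
mvkvct fixtures --outdir fixtures/       # small seeded test inputs
```

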