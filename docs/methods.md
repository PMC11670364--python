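# Methods

## Scope and model

The package models a dual-source CT acquisition pairing a detuned 6-MV
treatment beam with an 80-kVp diagnostic beam, detected either by an
energy-integrating detector (EID, response `D(E) = E` in keV, electronic
readout noise `sigma_e = 10` counts) or a non-spectral photon-counting
detector (PCD, `D(E) = 1`, `sigma_e = 0`). Both detectors share one
detective-efficiency curve `eta(E)` so that only the weighting scheme and
electronic noise differ between them. Two complementary analyses are built
on the same signal model: a single-ray Cramér–Rao bound (CRLB) study of
basis-material SNR, and a full fan-beam CT simulation with sinogram-domain
material decomposition.

All energies are keV, lengths cm, densities g/cm³, mass thicknesses g/cm²,
dose µGy. A `Spectrum` stores photons **per energy bin per ray** (bin width
already integrated), so spectral integrals are plain sums and per-bin
Poisson sampling is direct.

## Spectra and efficiency (analytic stand-ins)

Measured beam spectra for this class of system are not generally
published, so both beams default to analytic models that reproduce the
beams' stated summary properties, and both are replaceable by two-column
text files.

* **kV beam**: Kramers bremsstrahlung photon fluence `∝ (kVp - E)/E`
  filtered by 2.5 mm Al, on a 1-keV grid from 10 keV to the tube potential
  (80 kVp default). Mean energy 40.4 keV. This shape is softer than a
  measured tube spectrum at equal filtration (no anode self-filtration or
  characteristic lines).
* **MV beam**: fluence `∝ E exp(-E/E0)` with `E0 = 1` MeV, truncated at
  6 MeV, on a 20-keV grid; the mode sits at ~1 MeV and the mean at
  1.91 MeV, matching a treatment beam detuned for imaging.
* **Efficiency**: `eta(E)` is 1.0 up to 150 keV and declines log-linearly
  in energy to 0.20 at 6 MeV — the only two anchors available for the
  high-efficiency megavoltage gas detector it emulates.

Both spectra are normalized at construction so one ray delivers 1 µGy to
the center of a 40-cm water cylinder. Dosimetry is primary-beam only:
energy fluence surviving 20 cm of water times the water mass
energy-absorption coefficient, with no scatter buildup — the normalization
target is a stated dose, not a transport model. Dose allocation rescales
the MV beam to a fraction `r` of a fixed per-ray total and the kV beam to
`1 - r`, conserving total dose to better than 1e-10 relative.

**Known consequences of the stand-ins.** With these defaults the
dose-optimized PCD-over-EID improvement surface spans ~22% to ~106% over
the tissue 10–50 cm x bone 0.1–10 cm grid, rather than the ~15–45% expected
of this system class. The thin-composition corner (~69% even with
`sigma_e = 0`) reflects the analytic MV model's spectral breadth — the EID
energy-weighting penalty grows with the spread of detected photon energies
— and the thick-composition corner reflects electronic noise dominating
both nearly extinguished beams at the 1-µGy/ray count normalization (at
10 µGy/ray the grid spans ~15–69%). For the same reason the optimal MV
fraction for bone behind 40 cm tissue + 10 cm bone comes out near 0.3
rather than ~0.5: the soft analytic kV beam dies faster behind thick bone,
so the optimizer compensates with kV dose. Sub-cm-bone behavior
(`r_opt ≈ 0.82–0.86`, "nearly 90%") and the saddle shape of the improvement
surface are reproduced. Dropping in measured spectra via the text format
removes this caveat; these numbers are left as the model produces them.

## Attenuation data

Mass-attenuation and mass-energy-absorption tables for water, ICRU-style
soft tissue (basis density 1.06), cortical bone (basis density 1.85), Si,
CdTe and Al span 10 keV–6 MeV as bundled plain-text files, transcribed from
standard reference values; interpolation is log-log, which keeps curves
positive and monotone-safe between samples. Requests outside the tabulated
range raise rather than extrapolate. Only the water table is load-bearing
for dosimetry and HU; the basis tables are used identically on the forward
and inverse sides, so decomposition round trips are insensitive to small
table errors. Physics anchors: 3 cm Si stops 22.7% and 3 cm CdTe 49.6% of
3-MeV photons with these tables.

## Single-ray CRLB

The likelihood is Gaussian with the model mean and a **fixed** variance
(`v_i` evaluated at the true thicknesses); the Fisher matrix omits the
variance-derivative term, the standard convention for detector-comparison
CRLBs. EID variance is the compound-Poisson second moment
`∫ I tau eta E² dE` plus `(sigma_e * Ebar_i)²`, where `Ebar_i` is the
incident spectrum's fluence-weighted mean energy; PCD variance equals the
expected counts. The allocation sweep uses r = 0.01…0.99 in steps of 0.01
with ties broken toward smaller r; sweeps reuse unit-dose ray moments, since
rescaling a spectrum scales the signal gradient linearly and the quantum
variance linearly while the electronic variance is fixed. Singular Fisher
matrices (e.g. identical spectra) raise rather than returning infinities.
The default SNR-surface grid is 17 linearly spaced tissue x 21
geometrically spaced bone thicknesses; the acceptance script uses a 9x11
version of the same grid to keep the sweep under a couple of minutes on one
core — the extremes move by <2% between the two resolutions.

## Phantoms and ray tracing

Phantoms are painter's-order lists of circles/ellipses. The IQ phantom is a
40-cm tissue cylinder (rho 1.06) with seven 3-cm bone inserts, densities
1.0–2.2 g/cm³, placed one per 360/7° on a 12-cm ring with the densest at 12
o'clock — the ring layout is a package convention (only sizes and densities
are prescribed); it is configurable. The torso phantom is a procedural
stand-in for a licensed anthropomorphic voxel phantom: an elliptical body
with two low-density lungs, a spine and lateral rib bones, sized so
central-ray tissue-equivalent paths stay within ~18–32 cm and
bone-equivalent paths under ~5 cm; a seed drives ±2% anatomical jitter.
Voxel phantoms can be imported from a flat float32 grid + JSON sidecar
(line integrals by fixed-step sampling, approximate by construction).

Chords are exact analytic ray–ellipse intersections. Painter's order is
honored by subtracting each primitive's overlap with every later primitive,
which is exact when the later primitives overlapping a common earlier one
are mutually disjoint — true for both bundled phantoms and asserted nowhere
else. Path lengths are reported as basis-equivalent thickness: a chord `L`
through density `rho` contributes `L * rho / rho_basis` to its basis
material. Scout thickness profiles trace the central channel's ray through
the isocenter over a view sweep; on the IQ phantom the per-insert
bone-equivalent peaks span 1.62–3.57 cm (3-cm chord x rho/1.85) while
near-tangent crossings contribute arbitrarily small values, so profile
claims are made about per-insert peaks, not all crossing views.

## CT forward model and noise

Equiangular fan beam: source radius 55 cm, detector at 100 cm, 800 channels
over 50° (channel 0 at -25°, centre channel exactly on the central ray),
views uniform over 360° starting at 12 o'clock. MV and kV acquisitions are
geometrically aligned independent sinograms (the physical 90° source offset
is immaterial once sinograms are recombined per ray). Expected signals
apply the polychromatic Beer–Lambert model per ray; noise is sampled per
energy bin — Poisson counts for the PCD; energy-weighted Poisson plus
additive Gaussian `sigma_e * Ebar` for the EID, in the CT simulation as in
the single-ray model — and clamped to 1e-6 of the air value so logarithms
stay defined. Exact per-bin sampling (rather than a Gaussian approximation)
is kept because MV counts behind thick anatomy reach the tens, where the
approximation fails.

## Decomposition

Per pixel, the two log-transmission measurements `L_i = ln(air_i/meas_i)`
are matched to the model `M_i(A) = ln(lambda_i(0)/lambda_i(A))` —
an exactly determined 2x2 nonlinear system. Gauss–Newton with step halving
starts from the closed-form solve with fluence-weighted effective
attenuation coefficients; convergence at max-update < 1e-8 g/cm² or
residual < 1e-10, cap 50 iterations (noiseless IQ sinograms converge in 4).
Because the system is exactly determined, the estimator is
weighting-independent and asymptotically efficient — its high-flux variance
meets the CRLB, which the tests verify by Monte Carlo. Negative estimates
are deliberately permitted: clamping would bias the estimator under noise.
All pixels iterate simultaneously (vectorized, chunked), so a 360x800
sinogram pair decomposes in seconds.

## Reconstruction and analysis

Equiangular fan-beam FBP: cosine pre-weighting by `D cos(gamma)`, the
Ram-Lak kernel with the `(gamma/sin gamma)²` fan correction applied in the
frequency domain on zero-padded rows with a hard cutoff at 80% of the
channel Nyquist frequency (no apodization), then `1/L²`-weighted
backprojection over the full rotation. A uniform-disk oracle reconstructs
to 0.15% of truth at 256²/360 views. VMI synthesis and HU conversion are
pixelwise; reconstruction linearity makes VMI synthesis commute with FBP.

ROIs: insert ROI = the known insert disk eroded 2 pixels (erosion dropped
below ~6-pixel insert radii so miniature test problems stay valid);
background = a thin annulus at the insert-ring radius with dilated inserts
excluded, grown to at least one insert ROI's area. For noise-texture
comparisons the "tissue away from bone" reference is an annulus at
r = 15–19 cm: the cylinder center sits at the crossing of the inter-insert
streaks and is itself noise-elevated.

## Study sizes and reproducibility

The bundled reduced CT study uses 360 views, a 256² matrix and five noisy
realizations per detector at 10 mGy total with r = 0.85 — enough to resolve
the detector ordering of VMI CNR (PCD above EID at every monoenergy in
20–120 keV) and the sign of the noisy bone-density bias, while a full
1200-view, 512², 20-realization study is a configuration change away. All
randomness flows from one root seed split per stage
(`numpy.random.SeedSequence`), so identical configurations produce
byte-identical artifact manifests. The measured noisy-density bias is
negative but small (~0.1% of density) at these count levels; it is asserted
as a sign, not a magnitude.

## Limitations

No photon scatter, detector spatial-resolution physics, charge sharing,
pile-up, K-escape, bowtie filtration or focal-spot blur; 2-D geometry only;
analytic spectra as above. The synthetic torso emulates thickness
statistics, not anatomy — results on it demonstrate pipeline behavior, not
clinical image quality.
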