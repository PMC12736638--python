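# Methods

## The physical question and the model chain

A differential microwave imaging system records multi-port scattering
matrices of a scene twice — a reference ("healthy") state and a state under
test — and images only the change.  Subtracting the matrices cancels every
static contribution (antenna coupling, phantom shell, cables), so the
residual is dominated by whatever moved or changed dielectric state.  The
package models a specific instance: a cylindrical water phantom with an
8-mm-diameter water inclusion whose temperature, hence permittivity, drifts
in 0.1 °C steps, probed by a four-antenna array over 0.5–3 GHz.

## Dielectric model of water

The complex relative permittivity of deionized water follows a single-pole
Debye relaxation

    eps(f, T) = eps_inf(T) + (eps_s(T) − eps_inf(T)) / (1 + j 2π f τ(T)),

with eps = eps′ − j eps″ (eps″ ≥ 0) and the effective conductivity
σ = 2π f ε₀ eps″ (no static ionic term: deionized water has σ → 0 at low
frequency).  Two published coefficient sets are bundled:

* `stogryn1971` (default): zero-salinity polynomial fits for eps_s(T) and
  2πτ(T) with eps_inf = 4.9.
* `kaatze1989`: log-linear eps_s(T), linear eps_inf(T), Arrhenius τ(T).

Both sets reproduce published two-significant-figure per-0.1 °C sensitivity
tables for the 26.0→36.5 °C protocol to within a few percent, but they
bracket those values (Stogryn ~1–4.5% low, Kaatze ~2–6% high); the exact
coefficient set behind such tables is generally not recoverable from printed
two-digit values.  Stogryn is the default because it has the smaller
worst-case deviation and satisfies the R² > 0.985 linearity bound.  The
spread between standard fits — not numerical error — is the dominant
uncertainty of every dielectric quantity this package reports.

Sensitivity conventions (26.0 → 36.5 °C, n_T = 105 steps of 0.1 °C):

* η_εr = (εr(26) − εr(36.5)) / (n_T · εr(26)), in percent.  The cold-end
  value is the stable normalization because the properties decrease with T.
* η_σ = (σ(26) − σ(36.5)) / (n_T · εr(26)), in percent — the conductivity
  change is referenced to the *relative permittivity* at 26 °C, not to σ
  itself.  σ of deionized water approaches zero at the low band edge, so
  self-normalization diverges there and would make the column useless for
  band averaging; referencing εr yields finite, frequency-comparable
  figures and matches the convention of the published tables this module
  reproduces (those printed values scale as f², which only the
  εr-referenced convention produces).

Linearity is quantified by R² = 1 − SS_res/SS_tot of an ordinary
least-squares line on a 25–50 °C grid with 0.5 °C steps; the statistic is
insensitive to grid density for near-linear data, and degenerate inputs
(constant y, SS_tot = 0) raise rather than returning a silent 1 or NaN.

## Geometry

Coordinates are millimeters in the transverse plane, origin at the shared
center of array, ROI and phantom.  The four antennas form two pairs with
35° separation inside a pair and 90° between corresponding antennas of the
two pairs; apertures sit on the 100-mm circle.  Only the relative angles are
physically constrained; the default absolute orientation places antenna 1 at
107.5°, so the array's sensitivity axis bisects the pairs and covers the
inclusion at (−25, 10) mm.  Orientation is configurable and all pairwise
relations are rotation invariant.

The effective radiating point of a horn-type antenna (its phase center) sits
inside the aperture and moves with frequency.  It is modeled as
`aperture_radius − p(f)` along the boresight, with p a polynomial of degree
≤ 5 in frequency (GHz), evaluated only inside the 0.5–3 GHz design band (no
extrapolation).  The default polynomial is zero — radiating point at the
aperture — because fitted coefficients belong to a specific antenna design;
the forward model and the reconstruction share the same array object, so
simulation/reconstruction consistency holds for any choice.

The ROI grid is a square lattice (default 1-mm pitch, one pixel = 1 mm²)
clipped to the 100-mm circle: 31 417 focal points, symmetric under
reflection about either axis, containing the origin.

## Synthetic data generator

The generator emulates the statistical structure of the cooling experiment;
its defaults are the experiment's protocol values:

* sweep 0.5–3 GHz, 201 points; 4×4 complex S-matrix per point;
* 46 acquisitions at inclusion temperatures 40.5, 40.4, …, 36.0 °C inside a
  25 °C background (the first acquisition is the reference);
* acquisition timestamps from a two-phase timing model — the first 23
  intervals N(4.78 s, 0.99 s), the remaining 22 N(5.77 s, 0.68 s) — because
  cooling slows as the target approaches room temperature; the deterministic
  means give a 237 s total and a 5.26 s mean interval;
* transmission forced below −80 dB with randomized phase above 2.3 GHz,
  reproducing the measured collapse of the usable band.  The replacement is
  seeded per sweep specification, not per acquisition, so it cancels exactly
  in differential processing — as the physical high band effectively does;
* additive circular complex Gaussian noise per matrix entry at a
  configurable floor (default −100 dB).  Noise draws are independent per
  acquisition via spawned seed sequences; a series is bit-reproducible from
  its seed.

The scattered field uses a first-order 2D Born approximation with line
sources at the antenna radiating points:

    S_scat(Ti, Rj; f) = k² ∫_inclusion Δχ G(r_Ti, r) G(r, r_Rj) dA,

with Δχ = (ε_inc − ε_bg)/ε_bg, G(r, r′) = −(j/4) H₀⁽²⁾(k|r−r′|), and k the
*complex* background wavenumber at 25 °C (losses make the high-frequency
channel decay naturally).  The inclusion is discretized at 0.25-mm cells
(≥16 cells across the 8-mm diameter, converged for these smooth kernels; a
cell larger than radius/4 is rejected).  Born linearization is well
justified for the thermal study: the inclusion contrast is below 2% even at
the full 4.5 °C span.  The air-filled validation target (Δχ ≈ −1) stretches
the approximation and is used for localization only, not amplitude accuracy.
The Teflon tube wall and the phantom shell are omitted: identical in both
states, they cancel exactly in ΔS.

The target-free baseline coupling is a line-source channel through the lossy
background scaled by 0.1, giving in-band transmission magnitudes of roughly
−40 to −57 dB — plausible for submerged antennas — and, like every static
term, irrelevant after subtraction.  Diagonal (reflection) entries carry a
smooth placeholder ripple and are never used by the imaging chain.

What the generator does **not** emulate: multiple scattering, antenna
mismatch and drift, cable/connector systematics, VNA phase noise with 1/f
structure, or mechanical vibration.  Passing tests therefore demonstrate
the correctness and sensitivity scaling of the processing chain under the
stated noise model, not the absolute hardware threshold of any real system.

## Reconstruction (MFBF)

For each focal point the differential data are focused as

    I(x, y) = Σ_f Σ_{Ti,Rj} ΔS_TiRj(f) / k(f)² · e^{jkρ_Rj} · e^{jkρ_Ti},

with k = 2πf√εr/c from the *real* background permittivity at 25 °C (losses
are excluded from the focusing kernel; the image is a qualitative contrast
indicator) and ρ the Euclidean distances to the frequency-dependent
radiating points.  The positive exponents compensate the e^{−jkρ}
propagation phase of the forward model, so the true scatterer location adds
coherently over the 121 in-band frequencies and the six unique transmission
channels {(1,2),(1,3),(1,4),(2,3),(2,4),(3,4)}.  Reciprocal duplicates are
excluded by default (they duplicate information; a doubled constant would be
absorbed by normalization), as are reflection terms.  A configuration switch
flips the exponent signs for data recorded under the opposite phase
convention.  Division is by k², not |k|² (identical for the real k used
here).  Display uses |I|; the complex image is retained, which keeps the
transform exactly linear in ΔS.  Ties in the argmax resolve to the lowest
linear pixel index and are logged.

## Detection analysis

* **Localization error**: distance from the argmax of |I| to the true
  inclusion center; invariant under positive rescaling of the image.
* **Peak regression**: least-squares line of peak |I| against ΔT.  Peaks
  enter *un-normalized*: per-image normalization would erase the linear
  trend being quantified.  Noise-free synthetic series give R² > 0.999
  (Born linearity composed with the near-linear ε(T)).
* **Detection threshold**: the smallest sampled ΔT from which the
  localization error stays within tolerance for every larger ΔT; the
  default tolerance is the 4-mm inclusion radius + 5 mm.  An
  emergence-of-a-peak judgment made visually in laboratory practice is
  replaced by this reproducible, monotone criterion.
* **Contrast conversion**: threshold °C × band-averaged per-0.1 °C
  sensitivities (0.5–2 GHz rows of the sensitivity table) × 10 steps/°C,
  yielding % contrast in εr and σ; exactly linear in ΔT.
* **Noise calibration**: the synthetic noise floor that stands in for
  unreported hardware noise is derived, not fitted: the noise-free image
  peak is linear in ΔT and the noise-only image peak is linear in the noise
  amplitude, so setting them equal at ΔT = 0.35 °C (midway between the
  0.3 °C and 0.4 °C protocol steps) fixes the floor (≈ −97.5 dB for the
  default scene, close to the generator's −100 dB default).  Individual
  noise realizations then scatter the threshold by about one step around
  0.4 °C; the reported threshold is the median over seeds, and thresholds
  are non-increasing in SNR.

## Thermal budget

Lumped heat balance with c_p = 4186 J/(kg·°C): capacities C = m c_p for the
3.46 kg bath (π·0.105²·0.1 m³) and the 7.85 g target water column (the
tube's 5-mm outer radius × 100 mm; this is the mass consistent with the
reported ~7.8 g, rather than the 4-mm bore alone); released heat
Q = C_target·4.5 °C ≈ 148 J; conservative bulk rise Q/C_phantom ≈ 0.01 °C;
convective time constant τ = ρc_pV/(hA) with A the **full** cylinder surface
(lateral + both ends — the reading consistent with the quoted 6→3 h range
for h = 5→10 W m⁻² K⁻¹).  Both results confirm the background is thermally
static on the experiment's ~4-minute timescale.

## Numerical and design choices

* Sign conventions: e^{+jωt} time dependence; ε = ε′ − jε″; outgoing 2D
  Green's function −(j/4)H₀⁽²⁾(kr) with Im k < 0, so fields decay with
  distance and σ ≥ 0.
* Quadrature lattices (inclusion cells, ROI pixels) are axis-aligned and
  centered, so 90°-rotation/reflection symmetries of the geometry are exact
  to machine precision; congruences requiring other rotations hold to
  quadrature convergence (~10⁻³ relative at 0.25-mm cells).
* Degenerate inputs raise typed errors (`ConfigError`, `DataError`,
  `ComputationError`, mapped to CLI exit codes 2/3/4) rather than returning
  sentinel values: all-zero images, constant regressions, inverted bands,
  out-of-range temperatures.
* Problem sizes: tests run most properties on a 2-mm ROI grid (7 845
  pixels) and the full-pipeline checks on the production 1-mm grid (31 417
  pixels, 121 frequencies, 6 channels, 46 acquisitions) — the production
  configuration itself, chosen to keep a full study run in seconds per
  series.
* Determinism: every stochastic stage (acquisition noise, timing, high-band
  phases, calibration noise realizations) derives from explicit integer
  seeds through `numpy` seed sequences; rerunning with the same seed
  reproduces results bit-exactly.

## Known limitations

* 2D scalar model: no out-of-plane propagation, polarization, or antenna
  pattern weighting; the phase-center polynomial is an interface, with zero
  default.
* Born linearity means the synthetic air-target case validates geometry,
  not amplitudes.
* The detection threshold under calibrated noise reproduces the *mechanism*
  of a hardware-limited threshold; the absolute dB floor of a real system is
  not predicted.
* Single-Debye water: accurate below ~25 GHz for pure water; ionic
  conductivity of real tissue-mimicking liquids is out of scope.
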