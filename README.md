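# dmwi — differential microwave imaging of temperature-controlled phantoms

`dmwi` is a research pipeline for a phantom-based feasibility question in
biomedical microwave imaging (MWI): *how small a dielectric contrast can a
compact four-antenna differential imaging system detect?*  The question is
motivated by early Parkinson's disease, where degeneration of the substantia
nigra pars compacta (SNpc, an ~8-mm midbrain nucleus) is expected to produce
small, lateralized dielectric changes.  Because those changes are not yet
quantified in tissue, the system's sensitivity is characterized on a
water-filled cylindrical head phantom in which an off-center water column is
heated and allowed to cool: the temperature dependence of water's complex
permittivity turns a 0.1 °C step into a small, repeatable, well-known
dielectric contrast.

The package implements the full chain:

* **Dielectrics.**  Single-pole Debye relaxation of water,
  ε(f, T) = ε∞(T) + (ε_s(T) − ε∞(T)) / (1 + j2πf τ(T)),
  with the convention ε = ε′ − jε″ and σ = 2πf ε₀ ε″.  Over 25–50 °C both
  ε_r(T) and σ(T) are nearly linear (R² > 0.985 at 0.5–3 GHz), so temperature
  is a clean linear dial for contrast.  Per-0.1 °C relative sensitivities
  η_εr, η_σ are tabulated for the 26.0→36.5 °C probe protocol (n_T = 105
  steps).
* **Geometry.**  Four antennas in two 35°-separated pairs, the pairs 90°
  apart, apertures on a 100-mm circle; a 1-mm-pitch circular region of
  interest (ROI, radius 100 mm); frequency-dependent phase-center offsets via
  an injectable polynomial.
* **Synthetic data.**  A first-order 2D Born forward model (line sources,
  lossy-background Green's functions) generates 4×4 scattering matrices over
  0.5–3 GHz (201 points) for the cooling protocol: 46 acquisitions while the
  8-mm inclusion at (−25, 10) mm cools 40.5→36.0 °C in 0.1 °C steps inside
  25 °C water, with transmission forced below −80 dB above 2.3 GHz and a
  configurable complex-Gaussian noise floor.  Datasets round-trip through
  plain-text Touchstone `.s4p` files plus a manifest.
* **Reconstruction.**  Differential multi-frequency bi-focusing (MFBF):
  ΔS = S_background − S_target, then per focal point
  I(x, y) = Σ_f Σ_{Ti,Rj} ΔS_TiRj(f)/k² · e^{jkρ_Rj} · e^{jkρ_Ti},
  with k = 2πf√ε_r/c of the background and ρ the focal-point–antenna
  distances — a matched-filter back-propagation over the usable 0.5–2 GHz
  band (121 points) and the six transmission channels.
* **Analysis.**  Localization error, peak-vs-ΔT regression, an operational
  detection threshold (smallest ΔT from which the argmax stays within
  tolerance of the true target), conversion of thresholds into % contrast in
  ε_r and σ, and a lumped thermal budget of the phantom.

## Worked example

```
$ python analysis/01_dielectric_characterization.py     # sensitivities, R²
$ python analysis/02_simulate_cooling.py                # 46-acquisition dataset
$ python analysis/03_reconstruct_images.py              # MFBF images + peaks
$ python analysis/04_detection_analysis.py              # threshold study
$ python analysis/05_thermal_budget.py                  # heat balance
```

`04_detection_analysis.py` prints (seed 1):

```
noise-free series:
  peak-vs-dT regression R^2 = 0.999983
  max localization error = 0.0 mm
  detection threshold = 0.1 C (smallest simulated step: every contrast is visible without noise)

calibrated noise floor: -97.5 dB (noise-only image peak = signal peak at dT = 0.35 C)
  thresholds over 5 noise seeds: [0.5, 0.4, 0.2, 0.5, 0.4] -> median 0.4 C
  equivalent contrast: 0.167% in eps_r, 0.00456% in sigma
```

Reading: without noise the Born-linear system localizes every 0.1 °C step
perfectly and the image peak grows linearly with ΔT.  With the noise floor
calibrated so that contrasts below ≈0.35 °C drown in noise, the operational
threshold settles at 0.4 °C — equivalent to a relative permittivity contrast
of roughly 0.17% (and ~0.005% in conductivity), the figure of merit for the
system's sensitivity.

The same stages are available as a CLI (`dmwi simulate / reconstruct /
analyze / dielectrics-table / thermal-budget`) driven by a validated YAML
configuration; see `dmwi --help`.

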