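"""Sensitivity and detection-threshold analysis of the imaging system.

Three experiments, each on the full 46-acquisition series with the 1-mm grid:

1. noise-free: the peak magnitude grows linearly with dT and the argmax sits
   on the inclusion at every step — the intrinsic (noiseless) threshold is
   the smallest simulated step, 0.1 C;
2. calibrated noise: the floor is set so the noise-only image peak equals the
   signal peak at dT = 0.35 C; the detection threshold then lands at 0.4 C
   (median over noise seeds), emulating a hardware-limited system;
3. the threshold is converted to permittivity/conductivity contrast via the
   band-averaged per-0.1 C sensitivities.

Writes results/detection_noise_free.csv and results/detection_calibrated.csv.
"""

from pathlib import Path

import numpy as np

import dmwi
from dmwi.analysis import calibrate_noise_floor, detection_report
from dmwi.reconstruction import water_permittivity_fn

OUT = Path(__file__).resolve().parents[1] / "results"
TRUE_CENTER = (-25.0, 10.0)
SEED = 1


def run_series(scene, array, grid, medium, acq):
    series = dmwi.cooling_series(scene, array, acq)
    dsets = [dmwi.differential(series.background, s) for s in series.s_sets[1:]]
    images = dmwi.mfbf_image_series(dsets, array, grid, medium)
    table = dmwi.sensitivity_table()
    return detection_report(
        series.delta_t_c[1:], images, TRUE_CENTER, table=table
    )


def main() -> None:
    OUT.mkdir(exist_ok=True)
    array = dmwi.build_array()
    grid = dmwi.build_grid(100.0, 1.0)
    medium = water_permittivity_fn(dmwi.WATER_DEBYE["stogryn1971"], 25.0)
    scene = dmwi.PhantomScene(inclusion_temperature_c=40.5)

    quiet = dmwi.AcquisitionSpec(noise_floor_db=None, seed=SEED)
    rep = run_series(scene, array, grid, medium, quiet)
    rep.to_frame().to_csv(OUT / "detection_noise_free.csv", index=False)
    print("noise-free series:")
    print(f"  peak-vs-dT regression R^2 = {rep.regression.r_squared:.6f}")
    print(f"  max localization error = {rep.localization_error_mm.max():.1f} mm")
    print(f"  detection threshold = {rep.threshold_delta_t_c:.1f} C "
          "(smallest simulated step: every contrast is visible without noise)")

    floor = calibrate_noise_floor(scene, array, quiet, grid, medium, seed=SEED)
    print(f"\ncalibrated noise floor: {floor:.1f} dB "
          "(noise-only image peak = signal peak at dT = 0.35 C)")
    thresholds = []
    last = None
    for seed in range(5):
        acq = dmwi.AcquisitionSpec(noise_floor_db=floor, seed=seed)
        last = run_series(scene, array, grid, medium, acq)
        thresholds.append(last.threshold_delta_t_c)
    last.to_frame().to_csv(OUT / "detection_calibrated.csv", index=False)
    med_thr = float(np.median(thresholds))
    print(f"  thresholds over 5 noise seeds: {thresholds} -> median {med_thr:.1f} C")

    table = dmwi.sensitivity_table()
    eps_pct, sigma_pct = dmwi.threshold_to_contrast(med_thr, table)
    print(f"  equivalent contrast: {eps_pct:.3f}% in eps_r, "
          f"{sigma_pct:.5f}% in sigma")


if __name__ == "__main__":
    main()
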