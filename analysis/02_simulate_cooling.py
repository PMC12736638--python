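"""Simulate the cooling-inclusion experiment and write the dataset.

Generates the 46-acquisition synthetic S-parameter series (inclusion cooling
from 40.5 C to 36.0 C in 0.1 C steps inside 25 C water) with the default
noise floor, and writes Touchstone .s4p files plus a manifest under
results/dataset/.
"""

from pathlib import Path

import numpy as np

import dmwi
from dmwi import datasets

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    array = dmwi.build_array()
    acq = dmwi.AcquisitionSpec(seed=SEED)  # default -100 dB noise floor
    scene = dmwi.PhantomScene(inclusion_temperature_c=40.5)
    series = dmwi.cooling_series(scene, array, acq)
    manifest = datasets.save_series(series, OUT / "dataset")

    intervals = np.diff(series.acquisition_times_s)
    print(f"seed {SEED}: {len(series.s_sets)} acquisitions, "
          f"{acq.n_points} frequency points each")
    print(f"temperatures {series.temperatures_c[0]:.1f} -> "
          f"{series.temperatures_c[-1]:.1f} C in 0.1 C steps")
    print(f"total duration {series.acquisition_times_s[-1]:.0f} s; "
          f"mean interval {intervals.mean():.2f} s (sd {intervals.std(ddof=1):.2f} s)")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
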