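"""Lumped thermal budget of the phantom and the cooling target.

Confirms that the measurement protocol is thermally self-consistent: the
heat shed by the 7.8 g target while cooling by 4.5 C raises the 3.46 kg bath
by only ~0.01 C, and the bath's convective time constant (3-6 h for typical
laboratory air) dwarfs the ~4 min experiment.  Writes
results/thermal_budget.csv.
"""

from pathlib import Path

from dmwi.analysis import thermal_budget

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    budget = thermal_budget()
    frame = budget.to_frame()
    frame.to_csv(OUT / "thermal_budget.csv", index=False)
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        "\nbulk rise << 0.1 C resolution and tau >> experiment duration: "
        "the background water is effectively static during the protocol."
    )


if __name__ == "__main__":
    main()
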