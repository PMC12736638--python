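"""Cooling-series datasets on disk: Touchstone files plus a manifest.

A dataset directory holds one ``.s4p`` file per acquisition and a tab-separated
``manifest.tsv`` with columns (index, temperature_c, timestamp_s, filename),
which keeps the series order and metadata greppable without parsing the
Touchstone comments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from dmwi.errors import DataError
from dmwi.synthetic import CoolingSeries
from dmwi.touchstone import read_touchstone, write_touchstone

__all__ = ["save_series", "load_series", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.tsv"


def save_series(series: CoolingSeries, directory: str | Path) -> Path:
    """Write every acquisition and the manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sset in enumerate(series.s_sets):
        fname = f"acq_{i:03d}_T{sset.temperature_c:.1f}C.s4p"
        write_touchstone(sset, directory / fname)
        rows.append(
            {
                "index": i,
                "temperature_c": round(float(sset.temperature_c), 6),
                "timestamp_s": float(sset.timestamp_s),
                "filename": fname,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_series(directory: str | Path) -> CoolingSeries:
    """Read a dataset directory back into a :class:`CoolingSeries`."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise DataError(f"no {MANIFEST_NAME} in {directory}")
    table = pd.read_csv(manifest, sep="\t")
    required = {"index", "temperature_c", "timestamp_s", "filename"}
    if not required.issubset(table.columns):
        raise DataError(
            f"{manifest}: manifest must have columns {sorted(required)}"
        )
    table = table.sort_values("index")
    sets = []
    for _, row in table.iterrows():
        sset = read_touchstone(directory / row["filename"])
        if sset.temperature_c is None:
            sset.temperature_c = float(row["temperature_c"])
        if sset.timestamp_s is None:
            sset.timestamp_s = float(row["timestamp_s"])
        sets.append(sset)
    return CoolingSeries(
        temperatures_c=table["temperature_c"].to_numpy(dtype=float),
        acquisition_times_s=table["timestamp_s"].to_numpy(dtype=float),
        s_sets=sets,
    )
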