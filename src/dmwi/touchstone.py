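"""Plain-text Touchstone ``.s4p`` input/output.

Writes and reads 4-port network data in the classic Touchstone 1.x layout:
an option line ``# HZ S RI R 50``, ``!`` comment lines carrying acquisition
metadata (inclusion temperature, timestamp), and, per frequency point, four
data lines of four real/imaginary pairs (one matrix row per line, the first
prefixed by the frequency).  Round-tripping preserves frequencies and
matrices to better than 1e-9 relative error.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from dmwi.errors import DataError
from dmwi.synthetic import SParameterSet

__all__ = ["write_touchstone", "read_touchstone"]

_META_RE = re.compile(r"^!\s*(temperature_c|timestamp_s)\s*=\s*(\S+)")


def write_touchstone(sset: SParameterSet, path: str | Path) -> Path:
    """Write a 4-port :class:`SParameterSet` as Touchstone RI/Hz/50-ohm."""
    if sset.n_ports != 4:
        raise DataError(f"write_touchstone handles 4-port data, got {sset.n_ports}")
    path = Path(path)
    lines = ["! dmwi synthetic 4-port scattering data"]
    if sset.temperature_c is not None:
        lines.append(f"! temperature_c = {sset.temperature_c:.6g}")
    if sset.timestamp_s is not None:
        lines.append(f"! timestamp_s = {sset.timestamp_s:.6g}")
    lines.extend(f"! {c}" for c in sset.comments)
    lines.append(f"# HZ S RI R {sset.z0_ohm:g}")
    for f, m in zip(sset.frequencies_hz, sset.matrices):
        for row in range(4):
            head = f"{f:.9e}" if row == 0 else " " * 15
            vals = " ".join(
                f"{m[row, col].real: .12e} {m[row, col].imag: .12e}"
                for col in range(4)
            )
            lines.append(f"{head} {vals}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise DataError(f"cannot write Touchstone file {path}: {exc}") from exc
    return path


def read_touchstone(path: str | Path) -> SParameterSet:
    """Read a 4-port Touchstone file written by :func:`write_touchstone`.

    Accepts any RI-format ``.s4p`` with the 4-lines-per-frequency layout.
    Raises :class:`~dmwi.errors.DataError` naming the offending line for
    malformed headers or data.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read Touchstone file {path}: {exc}") from exc

    temperature = timestamp = None
    freq_unit = None
    z0 = 50.0
    numbers: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("!"):
            m = _META_RE.match(line)
            if m:
                if m.group(1) == "temperature_c":
                    temperature = float(m.group(2))
                else:
                    timestamp = float(m.group(2))
            continue
        if line.startswith("#"):
            tokens = line[1:].upper().split()
            if len(tokens) < 3 or tokens[1] != "S" or tokens[2] != "RI":
                raise DataError(
                    f"{path}:{lineno}: unsupported option line {line!r} "
                    "(need '# <unit> S RI [R z0]')"
                )
            scale = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}.get(tokens[0])
            if scale is None:
                raise DataError(f"{path}:{lineno}: unknown frequency unit {tokens[0]}")
            freq_unit = scale
            z0 = float(tokens[4]) if len(tokens) >= 5 and tokens[3] == "R" else 50.0
            continue
        try:
            numbers.extend(float(tok) for tok in line.split())
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: malformed data line {line!r}") from exc

    if freq_unit is None:
        raise DataError(f"{path}: missing '#' option line")
    values_per_point = 1 + 32  # frequency + 16 complex pairs
    if not numbers or len(numbers) % values_per_point:
        raise DataError(
            f"{path}: data length {len(numbers)} is not a whole number of "
            "4-port frequency blocks"
        )
    block = np.asarray(numbers, dtype=float).reshape(-1, values_per_point)
    freqs = block[:, 0] * freq_unit
    ri = block[:, 1:].reshape(-1, 4, 4, 2)
    matrices = ri[..., 0] + 1j * ri[..., 1]
    return SParameterSet(
        frequencies_hz=freqs,
        matrices=matrices,
        temperature_c=temperature,
        timestamp_s=timestamp,
        z0_ohm=z0,
    )
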