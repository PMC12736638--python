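"""Independent brute-force references used by the reconstruction tests.

Deliberately naive: scalar triple loops over frequency, channel, pixel,
written directly from the focusing definition with no shared code with the
package's vectorized implementation.
"""

import cmath
import math

from scipy.constants import c as C0


def brute_force_mfbf(dset, array, grid, medium, conjugate_focusing=False):
    """Triple-loop focusing sum; returns a list of complex pixel intensities."""
    freqs = [f for f, m in zip(dset.frequencies_hz, dset.band_mask) if m]
    data = dset.channel_data()  # (n_f_masked, n_ch)
    sign = -1.0 if conjugate_focusing else 1.0
    out = []
    for px, py in grid.pixel_centers_mm:
        total = 0.0 + 0.0j
        for fi, f in enumerate(freqs):
            k = 2.0 * math.pi * f * math.sqrt(medium(f)) / C0
            pos = array.positions(f)
            for ci, (ti, rj) in enumerate(dset.channels):
                rho_t = math.hypot(pos[ti][0] - px, pos[ti][1] - py) * 1e-3
                rho_r = math.hypot(pos[rj][0] - px, pos[rj][1] - py) * 1e-3
                total += (
                    data[fi, ci]
                    / k**2
                    * cmath.exp(sign * 1j * k * rho_r)
                    * cmath.exp(sign * 1j * k * rho_t)
                )
        out.append(total)
    return out
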