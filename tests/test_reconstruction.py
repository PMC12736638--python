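"""Differential processing and MFBF focusing."""

import numpy as np
import pytest
from scipy.constants import c as C0

import dmwi
from dmwi.errors import ComputationError, DataError
from dmwi.reconstruction import (
    DifferentialSet,
    differential,
    mfbf_image,
    select_band,
    wavenumber,
)
from dmwi.synthetic import TRANSMISSION_CHANNELS, born_transmission

from _oracles import brute_force_mfbf


@pytest.fixture(scope="module")
def thermal_pair(array, quiet_acq):
    bg = dmwi.simulate_sparams(
        dmwi.PhantomScene(inclusion_temperature_c=40.5), array, quiet_acq
    )
    tg = dmwi.simulate_sparams(
        dmwi.PhantomScene(inclusion_temperature_c=36.0), array, quiet_acq
    )
    return bg, tg


class TestDifferential:
    def test_identical_inputs_give_zero(self, thermal_pair):
        bg, _ = thermal_pair
        d = differential(bg, bg)
        assert np.all(d.delta_matrices == 0)

    def test_swapping_arguments_negates(self, thermal_pair):
        bg, tg = thermal_pair
        fwd = differential(bg, tg)
        rev = differential(tg, bg)
        assert np.array_equal(fwd.delta_matrices, -rev.delta_matrices)

    def test_mismatched_frequency_grids_rejected(self, array):
        acq_a = dmwi.AcquisitionSpec(n_points=11, noise_floor_db=None)
        acq_b = dmwi.AcquisitionSpec(n_points=13, noise_floor_db=None)
        scene = dmwi.PhantomScene(inclusion_temperature_c=40.5)
        a = dmwi.simulate_sparams(scene, array, acq_a)
        b = dmwi.simulate_sparams(scene, array, acq_b)
        with pytest.raises(DataError, match="frequency grids"):
            differential(a, b)

    def test_thermal_differential_matches_born_difference_oracle(
        self, array, quiet_acq, thermal_pair
    ):
        """In-band dS must equal the difference of the two Born contributions."""
        bg, tg = thermal_pair
        d = differential(bg, tg)
        f = d.frequencies_hz[40]
        pos = array.positions(f)
        hot = dmwi.PhantomScene(inclusion_temperature_c=40.5)
        cold = dmwi.PhantomScene(inclusion_temperature_c=36.0)
        for ci, (i, j) in enumerate(TRANSMISSION_CHANNELS):
            expected = born_transmission(hot, pos[i], pos[j], f) - born_transmission(
                cold, pos[i], pos[j], f
            )
            assert d.delta_matrices[40, i, j] == pytest.approx(expected, rel=1e-9)
            assert abs(d.delta_matrices[40, i, j]) > 0


class TestBandSelection:
    def test_default_band_is_121_of_201_points(self, thermal_pair):
        d = differential(*thermal_pair)
        assert d.n_band_points == 121
        assert len(d.frequencies_hz) == 201

    def test_full_sweep_selection(self, thermal_pair):
        d = select_band(differential(*thermal_pair), 0.5e9, 3.0e9)
        assert d.n_band_points == 201

    def test_inverted_bounds_rejected(self, thermal_pair):
        with pytest.raises(ComputationError, match="inverted"):
            select_band(differential(*thermal_pair), 2.0e9, 0.5e9)

    def test_empty_selection_rejected(self, thermal_pair):
        with pytest.raises(ComputationError, match="no sweep points"):
            select_band(differential(*thermal_pair), 3.5e9, 4.0e9)


class TestWavenumber:
    def test_vacuum(self):
        assert wavenumber(1.0e9, 1.0) == pytest.approx(2 * np.pi * 1e9 / C0)

    def test_square_root_scaling(self):
        assert wavenumber(1.0e9, 4.0) == pytest.approx(2 * wavenumber(1.0e9, 1.0))

    def test_water_at_1ghz_matches_hand_value(self, water):
        er = dmwi.debye_permittivity(1.0e9, 25.0, water).real
        assert wavenumber(1.0e9, er) == pytest.approx(
            2 * np.pi * 1.0e9 * np.sqrt(er) / C0, rel=1e-12
        )

    def test_nonpositive_permittivity_rejected(self):
        with pytest.raises(ComputationError):
            wavenumber(1.0e9, -1.0)


def _single_channel_dset(freqs_hz, delta_values):
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    mats = np.zeros((len(freqs_hz), 4, 4), dtype=complex)
    mats[:, 0, 1] = delta_values
    return DifferentialSet(
        frequencies_hz=freqs_hz,
        delta_matrices=mats,
        band_mask=np.ones(len(freqs_hz), dtype=bool),
        channels=((0, 1),),
    )


class TestMFBF:
    def test_zero_differential_gives_zero_image(self, array, coarse_grid, medium):
        d = _single_channel_dset(1.0e9, 0.0)
        img = mfbf_image(d, array, coarse_grid, medium)
        assert np.all(img.complex_intensity == 0)

    def test_matched_phase_peaks_at_chosen_pixel(self, array, coarse_grid, medium):
        """dS built as k^2 e^{-jk(rho_T + rho_R)} for one focal point adds
        coherently there across the sweep and must focus on that pixel;
        verified against a brute-force scan of every pixel."""
        freqs = np.linspace(0.5e9, 2.0e9, 16)
        target = np.array([-24.0, 10.0])  # a lattice point of the 2-mm grid
        pos = array.positions(freqs[0])
        k = np.array([wavenumber(f, medium(f)) for f in freqs])

        # single channel: the response is constant on the ellipse of equal
        # total path, so the target attains the grid maximum (possibly tied
        # along the ellipse)
        rho = (np.hypot(*(pos[0] - target)) + np.hypot(*(pos[1] - target))) * 1e-3
        d = _single_channel_dset(freqs, k**2 * np.exp(-1j * k * rho))
        img = mfbf_image(d, array, coarse_grid, medium)
        mags = np.abs(img.complex_intensity)
        target_idx = int(
            np.argmin(np.hypot(*(coarse_grid.pixel_centers_mm - target).T))
        )
        assert mags[target_idx] >= (1.0 - 1e-9) * mags.max()
        oracle = np.abs(brute_force_mfbf(d, array, coarse_grid, medium))
        assert oracle[target_idx] >= (1.0 - 1e-9) * max(oracle)

        # all six channels matched: the ellipses intersect only at the target,
        # which becomes the unique argmax
        mats = np.zeros((len(freqs), 4, 4), dtype=complex)
        for ti, rj in TRANSMISSION_CHANNELS:
            r = (np.hypot(*(pos[ti] - target)) + np.hypot(*(pos[rj] - target))) * 1e-3
            mats[:, ti, rj] = k**2 * np.exp(-1j * k * r)
        d6 = DifferentialSet(
            frequencies_hz=freqs,
            delta_matrices=mats,
            band_mask=np.ones(len(freqs), dtype=bool),
        )
        img6 = mfbf_image(d6, array, coarse_grid, medium)
        assert img6.peak_xy_mm == (-24.0, 10.0)

    def test_linearity_in_the_differential_data(
        self, array, coarse_grid, medium, thermal_pair
    ):
        bg, tg = thermal_pair
        d1 = differential(bg, tg)
        d2 = DifferentialSet(
            frequencies_hz=d1.frequencies_hz,
            delta_matrices=np.conj(d1.delta_matrices)[::-1].copy(),
            band_mask=d1.band_mask,
            channels=d1.channels,
        )
        alpha, beta = 2.0 - 1.0j, -0.5 + 0.25j
        combo = DifferentialSet(
            frequencies_hz=d1.frequencies_hz,
            delta_matrices=alpha * d1.delta_matrices + beta * d2.delta_matrices,
            band_mask=d1.band_mask,
            channels=d1.channels,
        )
        i1 = mfbf_image(d1, array, coarse_grid, medium).complex_intensity
        i2 = mfbf_image(d2, array, coarse_grid, medium).complex_intensity
        ic = mfbf_image(combo, array, coarse_grid, medium).complex_intensity
        assert np.allclose(ic, alpha * i1 + beta * i2, rtol=1e-12, atol=1e-20)

    def test_equals_brute_force_oracle_on_coarse_grid(
        self, array, medium, thermal_pair
    ):
        grid5 = dmwi.build_grid(100.0, 5.0)
        d = differential(*thermal_pair)
        img = mfbf_image(d, array, grid5, medium)
        oracle = np.asarray(brute_force_mfbf(d, array, grid5, medium))
        scale = np.abs(oracle).max()
        assert np.allclose(img.complex_intensity, oracle, atol=1e-10 * scale, rtol=1e-10)

    def test_air_target_localized_at_true_position(
        self, array, coarse_grid, medium, quiet_acq
    ):
        from dmwi.synthetic import air_permittivity

        bg = dmwi.simulate_sparams(
            dmwi.PhantomScene(inclusion_temperature_c=25.0), array, quiet_acq
        )
        tg = dmwi.simulate_sparams(
            dmwi.PhantomScene(
                inclusion_temperature_c=25.0, inclusion_medium=air_permittivity
            ),
            array,
            quiet_acq,
        )
        img = mfbf_image(differential(bg, tg), array, coarse_grid, medium)
        err = np.hypot(img.peak_xy_mm[0] + 25.0, img.peak_xy_mm[1] - 10.0)
        assert err <= 4.0, "argmax must fall inside the inclusion disk"

    def test_empty_band_or_channels_rejected(self, array, coarse_grid, medium):
        d = _single_channel_dset(1.0e9, 1.0)
        empty_band = DifferentialSet(
            frequencies_hz=d.frequencies_hz,
            delta_matrices=d.delta_matrices,
            band_mask=np.array([False]),
            channels=d.channels,
        )
        with pytest.raises(ComputationError, match="band"):
            mfbf_image(empty_band, array, coarse_grid, medium)
        no_channels = DifferentialSet(
            frequencies_hz=d.frequencies_hz,
            delta_matrices=d.delta_matrices,
            band_mask=d.band_mask,
            channels=(),
        )
        with pytest.raises(ComputationError, match="channel"):
            mfbf_image(no_channels, array, coarse_grid, medium)

    def test_conjugate_convention_conjugates_image_of_conjugate_data(
        self, array, coarse_grid, medium, thermal_pair
    ):
        d = differential(*thermal_pair)
        dc = DifferentialSet(
            frequencies_hz=d.frequencies_hz,
            delta_matrices=np.conj(d.delta_matrices),
            band_mask=d.band_mask,
            channels=d.channels,
        )
        img = mfbf_image(d, array, coarse_grid, medium)
        img_c = mfbf_image(dc, array, coarse_grid, medium, conjugate_focusing=True)
        assert np.allclose(img_c.complex_intensity, np.conj(img.complex_intensity))
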