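"""Synthetic-data generator: decay model, shot noise, fields, presets."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flimredox import (
    AcquisitionConfig,
    CellPreset,
    FieldLayout,
    model_decay_curve,
    simulate_field,
    simulate_histogram,
    species_preset,
)
from flimredox.errors import ParameterError, PlacementError


class TestModelDecayCurve:
    def test_normalised_and_positive(self, acq):
        c = model_decay_curve(0.7, 0.4, 3.0, acq)
        assert c.shape == (acq.n_bins,)
        assert c.min() >= 0
        assert np.isclose(c.sum(), 1.0)

    def test_pure_free_component_ignores_tau_bound(self, acq):
        c1 = model_decay_curve(1.0, 0.4, 1.0, acq)
        c2 = model_decay_curve(1.0, 0.4, 5.5, acq)
        np.testing.assert_allclose(c1, c2)

    def test_equal_lifetimes_collapse_to_mono(self, acq):
        mixed = model_decay_curve(0.5, 2.0, 2.0, acq)
        mono = model_decay_curve(1.0, 2.0, 2.0, acq)
        np.testing.assert_allclose(mixed, mono, atol=1e-12)

    def test_mean_arrival_matches_numerical_integration(self):
        # Independent oracle: direct Riemann integration of the
        # periodised bi-exponential (no FFT, no IRF machinery) shifted by
        # the (delta) IRF position.
        a1, tf, tb = 0.6, 0.4, 3.0
        acq = AcquisitionConfig(n_bins=2000, bin_width=6.25, irf_fwhm=1e-3, irf_center=1.0)
        c = model_decay_curve(a1, tf, tb, acq)
        mean_arrival = float((acq.bin_times() * c).sum())

        T = acq.period
        t = (np.arange(200_000) + 0.5) * (T / 200_000)
        decay = a1 * np.exp(-t / tf) / (1 - np.exp(-T / tf)) + (1 - a1) * np.exp(
            -t / tb
        ) / (1 - np.exp(-T / tb))
        shifted = np.mod(t + acq.irf_center, T)
        oracle = float((shifted * decay).sum() / decay.sum())
        assert mean_arrival == pytest.approx(oracle, abs=5e-3)

    def test_mean_arrival_limits_to_intensity_weighted_lifetime(self):
        # With the period much longer than the lifetimes, wrap-around is
        # negligible and the mean arrival time minus the IRF position is
        # the intensity-weighted lifetime (a1*tf^2+a2*tb^2)/(a1*tf+a2*tb).
        a1, tf, tb = 0.6, 0.4, 3.0
        acq = AcquisitionConfig(
            n_bins=8000, bin_width=12.5, period=100.0, irf_fwhm=1e-3, irf_center=1.0
        )
        c = model_decay_curve(a1, tf, tb, acq)
        mean_arrival = float((acq.bin_times() * c).sum()) - acq.irf_center
        tau_intensity = (a1 * tf**2 + (1 - a1) * tb**2) / (a1 * tf + (1 - a1) * tb)
        assert mean_arrival == pytest.approx(tau_intensity, abs=0.01)

    @pytest.mark.parametrize(
        "a1,tf,tb",
        [(np.nan, 0.4, 3.0), (0.5, np.inf, 3.0), (1.2, 0.4, 3.0), (0.5, 0.4, -1.0)],
    )
    def test_bad_parameters_rejected(self, acq, a1, tf, tb):
        with pytest.raises(ParameterError):
            model_decay_curve(a1, tf, tb, acq)


class TestSimulateHistogram:
    def test_zero_photons_zero_background(self, acq):
        h = simulate_histogram(np.full(acq.n_bins, 1 / acq.n_bins), 0, 0.0, 1, acq)
        assert h.n_photons == 0

    def test_negative_photons_rejected(self, acq):
        with pytest.raises(ParameterError):
            simulate_histogram(np.full(acq.n_bins, 1 / acq.n_bins), -1, 0.0, 1, acq)

    def test_seed_determinism(self, acq):
        c = model_decay_curve(0.7, 0.4, 2.5, acq)
        h1 = simulate_histogram(c, 1e4, 0.05, 42, acq)
        h2 = simulate_histogram(c, 1e4, 0.05, 42, acq)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_poisson_mean_over_replicates(self, acq, rng):
        # Mean total over replicates within 3 standard errors of the
        # analytic Poisson expectation n_photons + background*n_bins.
        c = model_decay_curve(0.7, 0.4, 2.5, acq)
        n, bg, reps = 2000.0, 0.1, 1000
        expected = n + bg * acq.n_bins
        totals = [
            simulate_histogram(c, n, bg, rng, acq).n_photons for _ in range(reps)
        ]
        se = np.sqrt(expected / reps)
        assert abs(np.mean(totals) - expected) < 3 * se


class TestSimulateField:
    def test_empty_field_is_background_only(self, km_preset, acq):
        layout = FieldLayout(image_shape=(64, 64), n_cells=0, seed=1)
        stack, gt = simulate_field(km_preset, layout, acq)
        assert len(gt) == 0
        expected_bg = acq.background_rate * acq.n_bins * 64 * 64
        assert abs(stack.counts.sum() - expected_bg) < 4 * np.sqrt(expected_bg)

    def test_photon_conservation(self, km_preset, acq):
        layout = FieldLayout(image_shape=(160, 160), n_cells=5, seed=2)
        stack, gt = simulate_field(km_preset, layout, acq)
        expected = (
            layout.n_cells * km_preset.photons_per_cell
            + acq.background_rate * acq.n_bins * 160 * 160
        )
        assert abs(stack.counts.sum() - expected) < 3 * np.sqrt(expected)

    def test_tau_mean_convexity_and_identity(self, km_preset, acq):
        layout = FieldLayout(image_shape=(200, 200), n_cells=10, seed=3)
        _, gt = simulate_field(km_preset, layout, acq)
        t = gt.table
        lo = np.minimum(km_preset.tau_free, t.tau_bound_true)
        hi = np.maximum(km_preset.tau_free, t.tau_bound_true)
        assert ((t.tau_mean_true >= lo) & (t.tau_mean_true <= hi)).all()
        np.testing.assert_allclose(
            t.tau_mean_true,
            t.a1_true * km_preset.tau_free + (1 - t.a1_true) * t.tau_bound_true,
        )

    def test_determinism_bit_identical(self, km_preset, acq):
        layout = FieldLayout(image_shape=(96, 96), n_cells=3, seed=9)
        s1, g1 = simulate_field(km_preset, layout, acq)
        s2, g2 = simulate_field(km_preset, layout, acq)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert g1.table.equals(g2.table)

    def test_overfull_layout_raises_placement_error(self, km_preset, acq):
        layout = FieldLayout(image_shape=(64, 64), n_cells=50, seed=0)
        with pytest.raises(PlacementError):
            simulate_field(km_preset, layout, acq)

    def test_masks_disjoint_and_inside(self, km_preset, acq):
        layout = FieldLayout(image_shape=(128, 128), n_cells=6, seed=4)
        _, gt = simulate_field(km_preset, layout, acq)
        total = np.zeros((128, 128), dtype=int)
        for m in gt.masks.values():
            total += m
        assert total.max() == 1  # no overlap


class TestPresets:
    def test_species_values(self, km_preset, sc_preset):
        assert km_preset.a1_mean == pytest.approx(0.690, abs=5e-4)
        assert sc_preset.a1_mean == pytest.approx(0.773, abs=5e-4)
        assert km_preset.tau_free == 0.4
        assert sc_preset.tau_free == 0.4

    def test_round_trip_reproduces_published_summaries(self):
        # Each preset's (a1, tau_bound) must give back the published
        # tau_mean and a1/a2 through the mixture identity to 2 d.p.
        for name, tm, ratio in [("kmarxianus", 1.21, 2.23), ("scerevisiae", 0.94, 3.40)]:
            p = species_preset(name)
            tau_mean = p.a1_mean * p.tau_free + (1 - p.a1_mean) * p.tau_bound_mean
            assert round(tau_mean, 2) == tm
            assert round(p.a1_mean / (1 - p.a1_mean), 2) == ratio

    def test_condition_presets_carry_tau_mean_targets(self):
        expected = {
            "km_30C": (0.94, 0.09),
            "km_45C": (1.10, 0.09),
            "km_h2o2": (1.12, 0.13),
            "km_control": (1.04, 0.07),
        }
        for name, target in expected.items():
            assert species_preset(name).tau_mean_target == target

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            species_preset("ecoli")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a1_mean=1.2),
            dict(tau_bound_mean=0.5),
            dict(tau_bound_mean=5.0),
            dict(photons_per_cell=10),
        ],
    )
    def test_preset_invariants_enforced(self, kwargs):
        base = dict(
            name="x", a1_mean=0.7, a1_sd=0.05, tau_free=0.4,
            tau_bound_mean=2.5, tau_bound_sd=0.3,
        )
        base.update(kwargs)
        with pytest.raises(ParameterError):
            CellPreset(**base)


class TestAcquisitionConfig:
    @given(
        n_bins=st.integers(10, 300),
        bin_width=st.floats(10.0, 60.0),
    )
    def test_bin_times_increasing_and_inside_window(self, n_bins, bin_width):
        try:
            acq = AcquisitionConfig(n_bins=n_bins, bin_width=bin_width)
        except ParameterError:
            return  # window exceeds period: correctly rejected
        t = acq.bin_times()
        assert np.all(np.diff(t) > 0)
        assert t[-1] < acq.period

    def test_window_must_fit_period(self):
        with pytest.raises(ParameterError):
            AcquisitionConfig(n_bins=500, bin_width=50.0, period=12.5)
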