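"""Generator contracts: determinism, conservation, planted statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smx import simulate
from smx.simulate import (TraceGroundTruth, TruncatedNormalPrecision,
                          generate_bleach_trace, generate_dimer_field,
                          generate_localization_field, generate_trace_set,
                          generate_two_channel_spots, render_image)


class TestBleachTraces:
    def test_no_steps_gives_constant_baseline(self):
        tr = generate_bleach_trace(TraceGroundTruth(0, baseline=100.0), 50)
        assert np.array_equal(tr, np.full(50, 100.0))

    def test_noiseless_single_step_levels(self):
        truth = TraceGroundTruth(1, (25,), (1000.0,), baseline=0.0)
        tr = generate_bleach_trace(truth, 50)
        assert np.array_equal(tr[:25], np.full(25, 1000.0))
        assert np.array_equal(tr[25:], np.zeros(25))

    def test_deterministic_under_fixed_seed(self):
        truth = TraceGroundTruth(3, (20, 50, 80), (900.0, 1000.0, 1100.0),
                                 baseline=100.0, noise_sd=50.0)
        a = generate_bleach_trace(truth, 120, seed=7)
        b = generate_bleach_trace(truth, 120, seed=7)
        assert np.array_equal(a, b)

    def test_step_frame_out_of_range_rejected(self):
        truth = TraceGroundTruth(1, (60,), (1000.0,))
        with pytest.raises(ValueError):
            generate_bleach_trace(truth, 50)

    @pytest.mark.parametrize("bad", [
        dict(n_steps=1, step_frames=(5, 6), step_heights=(1.0,)),
        dict(n_steps=2, step_frames=(6, 5), step_heights=(1.0, 1.0)),
        dict(n_steps=1, step_frames=(5,), step_heights=(-1.0,)),
    ])
    def test_invalid_ground_truth_rejected(self, bad):
        with pytest.raises(ValueError):
            TraceGroundTruth(**bad)


class TestTraceSet:
    def test_planted_weights_recovered_empirically(self):
        n = 20000
        w = (0.63, 0.24, 0.13)
        pairs = generate_trace_set(w, n, noise_sd=0.0, seed=4)
        counts = np.bincount([t.n_steps for _, t in pairs], minlength=4)[1:4]
        for k, wk in enumerate(w):
            tol = 3 * np.sqrt(wk * (1 - wk) / n)
            assert abs(counts[k] / n - wk) < tol

    def test_degenerate_weight_vector(self):
        pairs = generate_trace_set((1.0,), 50, seed=0)
        assert all(t.n_steps == 1 for _, t in pairs)

    def test_zero_traces_gives_empty_list(self):
        assert generate_trace_set((1.0,), 0, seed=0) == []

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            generate_trace_set((1.2, -0.2), 10, seed=0)

    def test_minimum_step_separation_enforced(self):
        pairs = generate_trace_set((0.0, 0.0, 0.0, 0.0, 1.0), 100, seed=9)
        for _, t in pairs:
            assert np.diff(t.step_frames).min() >= 24


class TestLocalizationField:
    def test_zero_precision_localizes_exactly(self):
        table, truth = generate_localization_field(
            n_clusters=1, stoichiometry_weights=(1.0,), blink_mean=1.0,
            precision_model=0.0, seed=1)
        assert len(table) == 1
        fl = truth.fluorophores.iloc[0]
        assert table["x_nm"].iloc[0] == pytest.approx(fl.x_nm)
        assert table["y_nm"].iloc[0] == pytest.approx(fl.y_nm)

    def test_fixed_seed_reproducible(self):
        t1, _ = generate_localization_field(n_clusters=20, seed=5)
        t2, _ = generate_localization_field(n_clusters=20, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fluorophore_conservation(self):
        table, truth = generate_localization_field(n_clusters=50, seed=2)
        assert truth.clusters["n_detected"].sum() == len(truth.fluorophores)
        # every localization maps to exactly one ground-truth fluorophore
        assert len(truth.localization_fluor_id) == len(table)
        blinks = truth.fluorophores.set_index("fluor_id")["n_blinks"]
        observed = pd.Series(truth.localization_fluor_id).value_counts()
        assert (observed.sort_index() == blinks.sort_index()).all()

    def test_every_fluorophore_emits(self):
        _, truth = generate_localization_field(n_clusters=30, seed=3)
        assert (truth.fluorophores["n_blinks"] >= 1).all()

    def test_precision_moments_match_model(self, rng):
        model = TruncatedNormalPrecision()
        draws = model.draw(rng, 10000)
        a = (model.lo_nm - model.mean_nm) / model.sd_nm
        b = (model.hi_nm - model.mean_nm) / model.sd_nm
        m, v = sps.truncnorm.stats(a, b, loc=model.mean_nm, scale=model.sd_nm,
                                   moments="mv")
        assert abs(draws.mean() - m) < 4 * np.sqrt(v / len(draws))
        assert draws.min() >= model.lo_nm and draws.max() <= model.hi_nm

    def test_negative_precision_model_rejected(self):
        with pytest.raises(ValueError):
            generate_localization_field(n_clusters=1, precision_model=-1.0, seed=0)

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError):
            generate_localization_field(n_clusters=100, field_size_nm=1000.0,
                                        min_cluster_separation_nm=600.0, seed=0)


class TestDimerField:
    def test_localization_error_consistent_with_precision(self):
        table, truth = generate_dimer_field(n_dimers=2000, separation_nm=40.0,
                                            precision_nm=10.0, seed=6)
        true_pos = truth.fluorophores.set_index("fluor_id")[["x_nm", "y_nm"]]
        pos = table[["x_nm", "y_nm"]].to_numpy()
        err = np.hypot(*(pos - true_pos.loc[truth.localization_fluor_id].to_numpy()).T)
        # mean radial error of isotropic Gaussian noise: sigma * sqrt(pi/2)
        expect = 10.0 * np.sqrt(np.pi / 2)
        se = 10.0 * np.sqrt((2 - np.pi / 2) / len(err))
        assert abs(err.mean() - expect) < 4 * se


class TestTwoChannel:
    def test_full_coincidence_zero_jitter_gives_identical_channels(self):
        a, b, _ = generate_two_channel_spots(200, 200, 1.0, jitter_sd=0.0, seed=1)
        assert np.array_equal(a, b)

    def test_zero_coincidence_has_no_planted_pairs(self):
        _, _, truth = generate_two_channel_spots(200, 200, 0.0, seed=1)
        assert len(truth.coincident_pairs) == 0

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_two_channel_spots(10, 10, 1.5, seed=0)

    def test_reproducible(self):
        a1, b1, _ = generate_two_channel_spots(100, 100, 0.3, seed=9)
        a2, b2, _ = generate_two_channel_spots(100, 100, 0.3, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


class TestRenderImage:
    def test_single_spot_peak_at_nearest_pixel(self):
        img = render_image([[30.0, 40.0]], intensities=[2000.0], shape=(64, 64),
                           background=100.0)
        y, x = np.unravel_index(np.argmax(img), img.shape)
        assert (x, y) == (30, 40)
        assert img[40, 30] == pytest.approx(2100.0)

    def test_empty_spot_list_gives_constant_background(self):
        img = render_image(np.empty((0, 2)), intensities=[], shape=(32, 32),
                           background=50.0)
        assert np.array_equal(img, np.full((32, 32), 50.0))

    def test_well_separated_spots_give_two_local_maxima(self):
        sigma = 1.5
        img = render_image([[20.0, 32.0], [35.0, 32.0]], intensities=[1000.0, 1000.0],
                           shape=(64, 64), psf_sigma=sigma, background=0.0)
        assert img[32, 20] == pytest.approx(1000.0, rel=1e-3)
        assert img[32, 35] == pytest.approx(1000.0, rel=1e-3)
        mid = img[32, 27]
        assert mid < 100.0  # deep valley between the maxima

    def test_out_of_bounds_spot_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            img = render_image([[100.0, 100.0]], intensities=[500.0], shape=(32, 32))
        assert np.array_equal(img, np.full((32, 32), 100.0))
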