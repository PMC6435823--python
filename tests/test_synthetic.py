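"""Generator contracts: determinism, distributions, forward-model arithmetic."""

import numpy as np
import pandas as pd
import pytest

from azquant import synthetic as syn


class TestAZMap:
    def test_single_az(self):
        m = syn.gen_az_map(1, seed=7)
        assert len(m) == 1
        assert 0.001 <= m.true_pr[0] <= 1.0

    def test_min_spacing_respected(self, default_map):
        from scipy.spatial.distance import pdist

        assert pdist(default_map.centers).min() >= 8.0

    def test_noise_free_coupling_is_monotone(self):
        m = syn.gen_az_map(50, coupling={"noise_sd": 0.0}, seed=3)
        order_level = np.argsort(m.true_level)
        assert np.all(np.diff(m.true_pr[order_level]) >= 0)

    def test_determinism(self):
        a = syn.gen_az_map(40, seed=11)
        b = syn.gen_az_map(40, seed=11)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_placement_failure_raises(self):
        with pytest.raises(RuntimeError):
            syn.gen_az_map(50, field=(30, 30), min_spacing=20.0, margin=5.0, seed=0)

    def test_median_pr_matches_monte_carlo_oracle(self, default_map):
        # oracle: many independent samples of the same size, coupling applied
        # per sample (normalization is per-sample), pooled median
        rng = np.random.default_rng(99)
        levels = 250.0 + rng.gamma(2.0, 300.0, size=(10000, 100))
        lo = levels.min(axis=1, keepdims=True)
        hi = levels.max(axis=1, keepdims=True)
        z = (levels - lo) / (hi - lo)
        pr = np.clip(0.5 * z + rng.normal(0.0, 0.03, levels.shape), 0.001, 1.0)
        oracle_median = np.median(pr)
        sample_median = np.median(default_map.true_pr)
        # tolerance: sampling error of a median at n = 100
        assert abs(sample_median - oracle_median) < 0.05

    def test_pr_distribution_matches_study_conditions(self):
        prs = np.concatenate([syn.gen_az_map(100, seed=s).true_pr for s in range(20)])
        assert 0.08 < np.median(prs) < 0.14
        assert np.mean((prs >= 0.01) & (prs <= 0.5)) > 0.85

    def test_second_channel_correlation(self):
        m = syn.gen_az_map(400, field=(1200, 1200), seed=5)
        r = np.corrcoef(m.true_level, m.second_level)[0, 1]
        assert 0.90 < r < 0.99


class TestRenderPuncta:
    def test_empty_map_is_background(self):
        m = syn.AZMap(
            az_id=np.array([], int), x=np.array([]), y=np.array([]),
            true_level=np.array([]), second_level=np.array([]),
            true_pr=np.array([]), field=(64, 64),
        )
        img = syn.render_puncta_image(m, background=20.0)
        assert np.all(img.pixels == 20.0)

    def test_noiseless_peak_at_center(self):
        m = syn.AZMap(
            az_id=np.array([0]), x=np.array([20.0]), y=np.array([30.0]),
            true_level=np.array([500.0]), second_level=np.array([500.0]),
            true_pr=np.array([0.1]), field=(64, 64),
        )
        img = syn.render_puncta_image(m, background=0.0)
        peak = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert peak == (30, 20)

    def test_integrated_intensity_equals_level(self):
        # oracle: analytic Gaussian integral (the kernel is normalized to unit sum)
        level = 777.0
        m = syn.AZMap(
            az_id=np.array([0]), x=np.array([32.0]), y=np.array([32.0]),
            true_level=np.array([level]), second_level=np.array([level]),
            true_pr=np.array([0.1]), field=(64, 64),
        )
        img = syn.render_puncta_image(m, background=5.0)
        total = img.pixels.sum() - 5.0 * img.pixels.size
        assert total == pytest.approx(level, rel=0.01)

    def test_total_intensity_linear_in_levels(self, default_map):
        img1 = syn.render_puncta_image(default_map, background=0.0)
        doubled = syn.AZMap(
            az_id=default_map.az_id, x=default_map.x, y=default_map.y,
            true_level=2 * default_map.true_level,
            second_level=default_map.second_level,
            true_pr=default_map.true_pr, field=default_map.field,
        )
        img2 = syn.render_puncta_image(doubled, background=0.0)
        np.testing.assert_allclose(img2.pixels, 2 * img1.pixels, rtol=1e-10)

    def test_center_outside_field_raises(self):
        m = syn.AZMap(
            az_id=np.array([0]), x=np.array([99.0]), y=np.array([5.0]),
            true_level=np.array([1.0]), second_level=np.array([1.0]),
            true_pr=np.array([0.1]), field=(64, 64),
        )
        with pytest.raises(ValueError):
            syn.render_puncta_image(m)


class TestReleaseTrials:
    def _one_az(self, pr):
        return syn.AZMap(
            az_id=np.array([0]), x=np.array([30.0]), y=np.array([30.0]),
            true_level=np.array([100.0]), second_level=np.array([100.0]),
            true_pr=np.array([pr]), field=(64, 64),
        )

    def test_pr_zero_gives_empty_stream(self):
        ev = syn.gen_release_trials(self._one_az(0.0), 50, seed=1)
        assert len(ev) == 0

    def test_pr_one_no_jitter_hits_every_stimulus_at_center(self, default_map):
        m = syn.AZMap(
            az_id=default_map.az_id, x=default_map.x, y=default_map.y,
            true_level=default_map.true_level, second_level=default_map.second_level,
            true_pr=np.ones(len(default_map)), field=default_map.field,
        )
        ev = syn.gen_release_trials(m, 5, jitter_sd=0.0, seed=2)
        assert len(ev) == 5 * len(m)
        per_stim = ev.events.groupby("stimulus_index").size()
        assert (per_stim == len(m)).all()
        assert np.allclose(np.sort(ev.events.query("stimulus_index == 0")["x"]), np.sort(m.x))

    def test_event_counts_match_binomial_oracle(self):
        # oracle: Binomial(100, 0.11) has mean 11, var 100*0.11*0.89
        m = self._one_az(0.11)
        counts = np.array(
            [len(syn.gen_release_trials(m, 100, seed=s)) for s in range(1000)]
        )
        se_mean = np.sqrt(100 * 0.11 * 0.89 / 1000)
        assert abs(counts.mean() - 11.0) < 3 * se_mean
        var = 100 * 0.11 * 0.89
        se_var = var * np.sqrt(2.0 / (1000 - 1))  # rough normal-approx SE of a variance
        assert abs(counts.var(ddof=1) - var) < 4 * se_var


class TestEventMovie:
    def test_no_events_gives_baseline_movie(self):
        ev = syn.EventStream(events=pd.DataFrame(columns=["stimulus_index", "x", "y"]), n_stimuli=3)
        mov = syn.render_event_movie(ev, (32, 32), background=7.0)
        assert np.all(mov.frames == 7.0)
        assert mov.n_stimuli == 3

    def test_flash_peak_at_event_coordinate(self):
        ev = syn.EventStream(
            events=pd.DataFrame({"stimulus_index": [0], "x": [10.0], "y": [20.0]}), n_stimuli=1
        )
        mov = syn.render_event_movie(ev, (32, 32), background=0.0)
        f = mov.frames[mov.stim_frames[0]]
        assert np.unravel_index(np.argmax(f), f.shape) == (20, 10)

    def test_geometric_decay(self):
        # oracle: closed-form geometric decay of the flash peak
        ev = syn.EventStream(
            events=pd.DataFrame({"stimulus_index": [0], "x": [16.0], "y": [16.0]}), n_stimuli=1
        )
        g = 0.4
        mov = syn.render_event_movie(
            ev, (32, 32), background=0.0, decay_ratio=g, decay_frames=3, flash_amplitude=100.0
        )
        f0 = mov.stim_frames[0]
        peak0 = mov.frames[f0].max()
        for k in (1, 2):
            assert mov.frames[f0 + k].max() == pytest.approx(peak0 * g**k, rel=1e-9)

    def test_decay_frames_precondition(self):
        ev = syn.EventStream(events=pd.DataFrame(columns=["stimulus_index", "x", "y"]), n_stimuli=1)
        with pytest.raises(ValueError):
            syn.render_event_movie(ev, (32, 32), decay_frames=1)


class TestPairedIntensities:
    def test_null_noiseless_identity(self, default_map):
        model = syn.PerturbationModel(mode="null")
        tr, veh = syn.gen_paired_intensities(default_map, model, n_vehicle_az=50, seed=1)
        np.testing.assert_array_equal(tr["after_raw"], tr["baseline"])
        np.testing.assert_array_equal(veh["after_raw"], veh["baseline"])

    def test_multiplicative_noiseless_exact(self, default_map):
        model = syn.PerturbationModel(mode="multiplicative", param=2.0)
        tr, _ = syn.gen_paired_intensities(default_map, model, n_vehicle_az=10, seed=1)
        np.testing.assert_allclose(tr["after_raw"], 2.0 * tr["baseline"], rtol=0)

    def test_multiplicative_ratio_constant_across_azs(self, default_map):
        model = syn.PerturbationModel(mode="multiplicative", param=1.3, vehicle_drift=0.9)
        tr, _ = syn.gen_paired_intensities(default_map, model, n_vehicle_az=10, seed=4)
        ratio = tr["after_raw"] / tr["baseline"]
        assert ratio.std() == pytest.approx(0.0, abs=1e-12)

    def test_additive_mean_shift_matches_oracle(self, default_map):
        # oracle: normal noise model — E[after - before] = c
        model = syn.PerturbationModel(mode="additive", param=10.0, noise_cv=0.05)
        tr, _ = syn.gen_paired_intensities(default_map, model, n_vehicle_az=10, seed=3)
        delta = tr["after_raw"] - tr["baseline"]
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean() - 10.0) < 3 * se

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            syn.PerturbationModel(mode="quadratic")


class TestTransientGenerator:
    def test_noiseless_peak_exact(self):
        rec = syn.gen_transient_recording(
            resting_R=2.0, delta_R=4.5, n_sweeps=1, noise_sd=0.0,
            train={"plateau_dR": 0.0},
        )
        assert rec.rhod.max() / rec.af647[0] == pytest.approx(6.5, abs=1e-9)

    def test_averaged_peak_recovers_amplitude_under_noise(self):
        # oracle: averaging n iid sweeps shrinks noise by 1/sqrt(n)
        from azquant.transients import analyze_transient

        rec = syn.gen_transient_recording(
            delta_R=4.5, tau=0.08, n_sweeps=10, noise_sd=0.02 * 4.5, seed=5
        )
        s = analyze_transient(rec)
        assert s.single_ap_delta_R == pytest.approx(4.5, rel=0.05)


class TestEphysGenerator:
    def test_zero_cv_gives_constant_mejps(self):
        rec = syn.gen_ephys_recording(mejp_mean=0.9, mejp_cv=0.0, seed=1)
        assert np.all(rec.mejp_amplitudes == 0.9)

    def test_quantal_content_recovered_at_large_n(self):
        rec = syn.gen_ephys_recording(
            mejp_mean=1.0, mejp_cv=0.3, n_mejps=5000, quantal_content=30.0, n_ejps=2000, seed=2
        )
        qc = rec.ejp_amplitudes.mean() / rec.mejp_amplitudes.mean()
        # oracle: law of large numbers; SE of the EJP mean dominates
        se = rec.ejp_amplitudes.std(ddof=1) / np.sqrt(len(rec.ejp_amplitudes))
        assert abs(rec.ejp_amplitudes.mean() - 30.0) < 3 * se + 0.1
        assert qc == pytest.approx(30.0, rel=0.05)

    def test_zero_mejps_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_ephys_recording(n_mejps=0)
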