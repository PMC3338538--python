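"""Generator tests: session designs, activation maps and the forward model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mazemvpa as mz
from mazemvpa.synthdata import (
    AcquisitionParams,
    NoiseParams,
    hrf_double_gamma,
    make_activation_patterns,
    make_exploration_design,
    make_imagery_design,
    required_scans,
    simulate_bold,
)


class TestExplorationDesign:
    def test_default_event_counts(self):
        ev = make_exploration_design(seed=0)
        counts = ev["trial_type"].value_counts()
        assert all(counts[c] == 135 for c in mz.CATEGORIES)
        assert ev["block"].nunique() == 15

    def test_stimulus_duration_fixed(self):
        ev = make_exploration_design(seed=1)
        assert (ev["duration"] == 3.0).all()

    def test_single_repetition(self):
        ev = make_exploration_design(n_repetitions=1, seed=0)
        assert len(ev) == 81
        assert ev["block"].nunique() == 3

    def test_block_category_order(self):
        ev = make_exploration_design(n_repetitions=1, seed=0)
        block0 = ev[ev["block"] == 0]["trial_type"].tolist()
        assert block0 == ["faces"] * 9 + ["buildings"] * 9 + ["animals"] * 9

    def test_fixation_gaps_within_range(self):
        ev = make_exploration_design(seed=2)
        # gap between last event of a block and first of the next
        firsts = ev.groupby("block")["onset"].min().to_numpy()
        lasts = (ev["onset"] + ev["duration"]).groupby(ev["block"]).max().to_numpy()
        gaps = firsts[1:] - lasts[:-1]
        assert np.all((gaps >= 15.0) & (gaps <= 18.0))

    def test_invalid_repetitions(self):
        with pytest.raises(ValueError):
            make_exploration_design(n_repetitions=0)

    def test_deterministic_given_seed(self):
        a = make_exploration_design(seed=5)
        b = make_exploration_design(seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestImageryDesign:
    def test_mean_path_length_with_full_recall(self):
        ev = make_imagery_design(recall_prob=(1, 1, 1), seed=0)
        assert ev.groupby("path").size().mean() == pytest.approx(4.5)

    def test_balanced_categories_with_full_recall(self):
        ev = make_imagery_design(recall_prob=(1, 1, 1), seed=3)
        counts = ev["trial_type"].value_counts()
        # 18 paths per category, lengths cycling 3,6,4,5 -> exactly 81 each
        assert all(counts[c] == 81 for c in mz.CATEGORIES)

    def test_imbalanced_recall_matches_expected_proportions(self):
        # expectation under per-image Bernoulli recall: p_c / sum(p)
        recall = (1.0, 0.65, 0.93)
        expected = np.array(recall) / np.sum(recall)
        counts = np.zeros(3)
        for seed in range(400):
            ev = make_imagery_design(recall_prob=recall, seed=seed)
            counts += [np.sum(ev["trial_type"] == c) for c in mz.CATEGORIES]
        props = counts / counts.sum()
        assert np.allclose(props, expected, atol=0.015)

    def test_durations_and_keypresses(self):
        ev = make_imagery_design(seed=1)
        assert ev["duration"].between(0.2, 4.0).all()
        assert (ev["response_time"] >= ev["onset"]).all()
        np.testing.assert_allclose(
            ev["response_time"], ev["onset"] + ev["duration"]
        )

    def test_paths_grouped_into_blocks_of_six(self):
        ev = make_imagery_design(seed=2)
        by_path = ev.groupby("path")["block"].first()
        assert (by_path == by_path.index // 6).all()

    def test_invalid_recall_probability(self):
        with pytest.raises(ValueError):
            make_imagery_design(recall_prob=(1.0, 1.2, 0.5))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_deterministic_given_seed(self, seed):
        a = make_imagery_design(n_tests=12, seed=seed)
        b = make_imagery_design(n_tests=12, seed=seed)
        pd.testing.assert_frame_equal(a, b)


class TestActivationPatterns:
    def test_zero_effect_gives_zero_maps(self):
        pat = make_activation_patterns(100, 10, 0.0, seed=0)
        assert not pat.maps.any()

    def test_disjoint_informative_sets_without_overlap(self):
        pat = make_activation_patterns(200, 20, 1.0, 0.0, seed=1)
        inf = pat.informative
        for a in mz.CATEGORIES:
            assert len(inf[a]) == 20
            for b in mz.CATEGORIES:
                if a < b:
                    assert len(np.intersect1d(inf[a], inf[b])) == 0

    def test_pairwise_overlap_counts(self):
        pat = make_activation_patterns(2000, 50, 1.0, 0.2, seed=2)
        inf = pat.informative
        for a in mz.CATEGORIES:
            assert len(inf[a]) == 50
            for b in mz.CATEGORIES:
                if a < b:
                    assert len(np.intersect1d(inf[a], inf[b])) == 10

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            make_activation_patterns(100, 50, 1.0, 0.0)


class TestSimulateBold:
    def test_zero_signal_zero_noise_is_constant_baseline(self):
        ev = make_exploration_design(n_repetitions=1, seed=0)
        params = AcquisitionParams(n_scans=required_scans(ev, 2.04), n_voxels=20)
        pat = make_activation_patterns(20, 2, 0.0, seed=0)
        silent = NoiseParams(white_sd=0, ar1_coef=0, drift_amp=0, motion_amp=0)
        sim = simulate_bold(ev, pat, params, noise=silent, seed=0)
        assert np.allclose(sim.data, 100.0)

    def test_components_sum_to_series(self):
        ev = make_exploration_design(n_repetitions=1, seed=1)
        params = AcquisitionParams(n_scans=required_scans(ev, 2.04), n_voxels=30)
        pat = make_activation_patterns(30, 3, 1.0, seed=1)
        sim = simulate_bold(ev, pat, params, seed=1)
        total = (
            sim.components["baseline"]
            + sim.components["evoked"]
            + sim.components["drift"]
            + sim.components["motion_effect"]
            + sim.components["noise"]
        )
        np.testing.assert_allclose(sim.data, total, rtol=1e-12)

    def test_evoked_component_linear_in_effect_size(self):
        ev = make_exploration_design(n_repetitions=1, seed=2)
        params = AcquisitionParams(n_scans=required_scans(ev, 2.04), n_voxels=30)
        sims = []
        for eff in (1.0, 2.0):
            pat = make_activation_patterns(30, 3, eff, seed=2)
            sims.append(simulate_bold(ev, pat, params, seed=2))
        np.testing.assert_allclose(
            sims[1].components["evoked"], 2.0 * sims[0].components["evoked"],
            rtol=1e-12,
        )

    def test_response_peak_matches_convolution_oracle(self):
        # independent oracle: direct numerical convolution of a 3 s boxcar
        # with the double-gamma response on a fine grid
        dt = 0.01
        t = np.arange(0, 40, dt)
        box = ((t >= 0) & (t < 3)).astype(float)
        h = hrf_double_gamma(np.arange(0, 32, dt))
        oracle_peak = t[np.argmax(np.convolve(box, h)[: len(t)])]

        ev = pd.DataFrame(
            {
                "onset": [10.0], "duration": [3.0], "trial_type": ["faces"],
                "block": [0], "response_time": [np.nan], "path": [np.nan],
            }
        )
        params = AcquisitionParams(tr=0.1, n_scans=500, n_voxels=3)
        pat = make_activation_patterns(3, 1, 1.0, seed=0)
        silent = NoiseParams(white_sd=0, ar1_coef=0, drift_amp=0, motion_amp=0)
        sim = simulate_bold(ev, pat, params, noise=silent, seed=0)
        vox = pat.informative["faces"][0]
        peak_t = params.scan_midpoints()[np.argmax(sim.data[:, vox])] - 10.0
        assert abs(peak_t - oracle_peak) < 0.2
        assert 5.0 < peak_t < 8.0  # haemodynamic delay scale

    def test_events_beyond_run_rejected(self):
        ev = make_exploration_design(n_repetitions=1, seed=0)
        params = AcquisitionParams(n_scans=10, n_voxels=10)
        pat = make_activation_patterns(10, 1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_bold(ev, pat, params, seed=0)

    def test_deterministic_given_seed(self):
        ev = make_exploration_design(n_repetitions=1, seed=4)
        params = AcquisitionParams(n_scans=required_scans(ev, 2.04), n_voxels=15)
        pat = make_activation_patterns(15, 2, 1.0, seed=4)
        a = simulate_bold(ev, pat, params, seed=9)
        b = simulate_bold(ev, pat, params, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.motion, b.motion)
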