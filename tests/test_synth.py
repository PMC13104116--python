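"""Generator tests: determinism, protocol counts and ground-truth validity."""

import dataclasses

import numpy as np
import pytest

from craniodyn.data import BACKGROUND
from craniodyn.respond import detect_responsive
from craniodyn.synth import (
    RecoveryScenario,
    SessionParams,
    build_schedule,
    make_atlas,
    morphology_series,
    simulate_cell_image,
    simulate_recovery,
    simulate_session,
)


class TestAtlas:
    def test_four_regions_on_square_sheet_tile_exhaustively(self):
        atlas = make_atlas(4, width=100.0, height=100.0)
        assert atlas.n_regions == 4
        xs, ys = np.meshgrid(np.linspace(0, 100, 21), np.linspace(0, 100, 21))
        labels = atlas.region_of(np.column_stack([xs.ravel(), ys.ravel()]))
        assert np.all(labels != BACKGROUND)
        assert set(labels) == {0, 1, 2, 3}

    def test_nineteen_regions_conserve_sheet_area(self):
        atlas = make_atlas(19)
        areas = (atlas.rects[:, 2] - atlas.rects[:, 0]) * (
            atlas.rects[:, 3] - atlas.rects[:, 1])
        assert np.all(areas > 0)
        assert np.isclose(areas.sum(), atlas.width * atlas.height)

    def test_deterministic_for_fixed_seed(self):
        a, b = make_atlas(19, seed=5), make_atlas(19, seed=5)
        np.testing.assert_array_equal(a.rects, b.rects)

    def test_outside_sheet_is_background(self):
        atlas = make_atlas(4, width=100.0, height=100.0)
        assert atlas.region_of([[150.0, 50.0]])[0] == BACKGROUND

    def test_too_many_regions_errors(self):
        with pytest.raises(ValueError, match="tile"):
            make_atlas(100, width=5.0, height=5.0)


class TestSchedule:
    def test_default_protocol_has_96_trials_24_per_orientation(self):
        params = SessionParams()
        sched = build_schedule(params, seed=0)
        assert sched.n_trials == 96
        for ori in (0.0, 45.0, 90.0, 135.0):
            assert len(sched.trials_of(ori)) == 24

    def test_single_rep_single_set_gives_one_trial_per_orientation(self):
        params = SessionParams(n_sets=1, reps_per_set=1)
        sched = build_schedule(params, seed=0)
        assert sched.n_trials == 4
        assert sorted(sched.orientations) == [0.0, 45.0, 90.0, 135.0]

    def test_isi_within_declared_range_and_gaps_respect_minimum(self):
        params = SessionParams()
        sched = build_schedule(params, seed=3)
        assert np.all(sched.isi >= 8.0) and np.all(sched.isi <= 10.0)
        gaps = np.diff(sched.onsets)
        assert np.all(gaps >= params.stim_duration + params.isi_range[0])

    def test_orientations_shuffled_within_each_set(self):
        params = SessionParams()
        sched = build_schedule(params, seed=4)
        per_set = len(params.orientations) * params.reps_per_set
        first_set = sched.orientations[:per_set]
        # balanced within the set, not blocked
        for ori in params.orientations:
            assert np.count_nonzero(first_set == ori) == params.reps_per_set

    def test_bit_reproducible(self):
        params = SessionParams()
        a, b = build_schedule(params, seed=9), build_schedule(params, seed=9)
        np.testing.assert_array_equal(a.onsets, b.onsets)
        np.testing.assert_array_equal(a.orientations, b.orientations)


class TestSession:
    def test_ground_truth_and_shapes(self, session, small_params, atlas):
        assert session.traces.shape[0] == small_params.n_neurons
        gt = session.ground_truth
        assert gt.responsive.shape == (small_params.n_neurons,)
        assert set(np.unique(gt.community)) <= set(range(small_params.n_communities))
        assert np.all(np.isin(gt.preferred_orientation, small_params.orientations))
        # labels reference the atlas
        assert np.all((session.regions >= 0) & (session.regions < atlas.n_regions))

    def test_bit_reproducible(self, small_params, atlas):
        sched = build_schedule(small_params, seed=1)
        a = simulate_session(small_params, sched, atlas, seed=2)
        b = simulate_session(small_params, sched, atlas, seed=2)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_infinite_kappa_limit_responds_to_single_orientation(self, atlas):
        params = dataclasses.replace(
            SessionParams(n_neurons=60), kappa=50.0, obs_noise=0.01,
            within_noise=0.0, between_noise=0.0, responsive_fraction=1.0)
        ds = simulate_session(params, build_schedule(params, seed=7),
                              atlas, seed=8)
        rset = detect_responsive(ds)
        # each neuron responsive to exactly its preferred orientation
        assert np.all(rset.flags.sum(axis=1) == 1)
        chosen = rset.orientations[rset.flags.argmax(axis=1)]
        np.testing.assert_array_equal(
            chosen, ds.ground_truth.preferred_orientation)

    def test_pure_noise_session_fires_detection_at_null_rate(self, noise_session):
        rset = detect_responsive(noise_session)
        assert rset.flags.mean() < 0.01

    def test_block_structure_without_global_coupling(self, atlas):
        """Neuron-level correlations are block-diagonal in expectation when
        communities share no global factor."""
        params = dataclasses.replace(
            SessionParams(n_neurons=45), responsive_fraction=0.0,
            between_noise=0.0, within_noise=0.3)
        within_vals, between_vals = [], []
        for seed in range(20):
            ds = simulate_session(params, build_schedule(params, seed=seed),
                                  atlas, seed=seed)
            W = np.corrcoef(ds.traces)
            comm = ds.ground_truth.community
            same = comm[:, None] == comm[None, :]
            off = ~np.eye(len(W), dtype=bool)
            within_vals.append(W[same & off].mean())
            between_vals.append(W[~same].mean())
        assert np.mean(within_vals) > 0.5
        assert abs(np.mean(between_vals)) < 0.05

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            SessionParams(decay_tau=0.0)
        with pytest.raises(ValueError):
            SessionParams(obs_noise=0.0)


class TestRecovery:
    def test_one_session_per_day_seeded_from_scenario(self):
        sc = RecoveryScenario(days=(1, 4, 7), session=SessionParams(n_neurons=20),
                              seed=3)
        a = simulate_recovery(sc)
        b = simulate_recovery(sc)
        assert list(a.sessions) == [1, 4, 7]
        np.testing.assert_array_equal(a.sessions[4].traces, b.sessions[4].traces)

    def test_morphology_series_encode_the_lag(self):
        sc = RecoveryScenario(lag_days=5.0, morph_noise_sd=0.0)
        series = morphology_series(sc)
        micro = next(s for s in series if s.modality == "microglial_intensity")
        neuro = next(s for s in series if s.modality == "neuronal_intensity")
        # noiseless: neuronal(t) equals the microglial curve at t - lag
        np.testing.assert_allclose(neuro.values, sc.micro_curve(neuro.days - 5.0))
        assert micro.values.argmax() == np.argmin(np.abs(micro.days - 10))

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            RecoveryScenario(lag_days=50.0)

    def test_eight_default_timepoints(self):
        assert len(RecoveryScenario().days) == 8


class TestCellImage:
    def test_star_geometry_and_determinism(self):
        a, _ = simulate_cell_image(6, 40.0, 5.0, seed=5)
        b, _ = simulate_cell_image(6, 40.0, 5.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_soma_only_when_no_processes(self):
        mask, center = simulate_cell_image(0, 40.0, 5.0, pixel_size=0.5, seed=0)
        rr, cc = np.nonzero(mask)
        dist = np.hypot(rr - center[0], cc - center[1]) * 0.5
        assert dist.max() <= 5.0 + 0.5

    def test_rays_beyond_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            simulate_cell_image(4, 300.0, 5.0, image_size=(128, 128),
                                pixel_size=0.5, seed=0)
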