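import numpy as np
import pytest

from dendropatch import dynamics as dyn
from dendropatch import simulate as sim
from tests._oracles import classify_oracle


def _track(onset, offset, length=1.5, origin=(0.0, 0.0), node_id=None):
    return dyn.ProtrusionTrack(
        onset, offset, np.full(offset - onset + 1, length), origin=origin, node_id=node_id
    )


def node_scene(n_from_node=8, n_total=10, seed=0):
    arcs = np.linspace(5, 45, n_total)
    prots, patches = [], []
    for i, a in enumerate(arcs):
        onset = 3 + (i % 3)
        prots.append(
            sim.ProtrusionEvent(
                float(a), onset, 1.5, 3.0, 2, 1.5,
                from_node_flag=i < n_from_node, side=1 if i % 2 else -1,
            )
        )
        if i < n_from_node:
            patches.append(
                sim.PatchEvent(float(a), max(onset - 2, 0), onset + 1, 1.0, 1.2,
                               node_flag=True)
            )
    cfg = sim.SceneConfig(
        n_frames=12, patch_events=patches, protrusion_events=prots,
        shaft_width_um=1.0, seed=seed,
    )
    return cfg, *sim.generate_scene(cfg)


class TestBinarize:
    def test_constant_frame_above_threshold_all_true(self):
        movie = dyn.binarize_movie(np.full((1, 4, 4), 10.0), 60, 0.2, threshold=5.0)
        assert movie.data.all()

    def test_threshold_above_max_all_false(self):
        movie = dyn.binarize_movie(np.full((2, 4, 4), 10.0), 60, 0.2, threshold=11.0)
        assert not movie.data.any()

    def test_scene_foreground_iou_against_ground_truth(self):
        cfg, stack, truth = node_scene()
        movie = dyn.binarize_movie(stack.channels["cytosol"], 60, cfg.pixel_size)
        for t in range(movie.n_frames):
            inter = (movie.data[t] & truth.frame_masks[t]).sum()
            union = (movie.data[t] | truth.frame_masks[t]).sum()
            assert inter / union >= 0.9

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            dyn.binarize_movie(np.empty((0, 4, 4)), 60, 0.2)


class TestTemporalColorCode:
    @staticmethod
    def _movie(n_frames, true_pixels):
        data = np.zeros((n_frames, 8, 8), bool)
        for t, (y, x) in true_pixels:
            data[t, y, x] = True
        return dyn.BinaryMovie(data, 60, 0.2)

    def test_single_frame_single_hue(self):
        import matplotlib

        movie = self._movie(1, [(0, (2, 2)), (0, (5, 5))])
        rgb = dyn.temporal_color_code(movie)
        expected = matplotlib.colormaps["jet"](0.0)[:3]
        np.testing.assert_allclose(rgb[2, 2], expected)
        np.testing.assert_allclose(rgb[5, 5], expected)
        assert np.all(rgb[0, 0] == 0)

    def test_pixel_true_only_in_frame_k_gets_frame_k_hue(self):
        import matplotlib

        movie = self._movie(10, [(4, (3, 3))])
        rgb = dyn.temporal_color_code(movie)
        np.testing.assert_allclose(rgb[3, 3], matplotlib.colormaps["jet"](4 / 9)[:3])

    def test_last_wins_for_multiply_active_pixel(self):
        import matplotlib

        movie = self._movie(10, [(2, (3, 3)), (7, (3, 3))])
        rgb = dyn.temporal_color_code(movie)
        np.testing.assert_allclose(rgb[3, 3], matplotlib.colormaps["jet"](7 / 9)[:3])

    def test_reversal_symmetry_only_for_single_frame_pixels(self):
        import matplotlib

        cmap = matplotlib.colormaps["jet"]
        movie = self._movie(10, [(2, (1, 1)), (2, (3, 3)), (7, (3, 3))])
        reversed_movie = dyn.BinaryMovie(movie.data[::-1], 60, 0.2)
        fwd = dyn.temporal_color_code(movie)
        rev = dyn.temporal_color_code(reversed_movie)
        # single-frame pixel: reversed overlay carries the mirrored hue
        np.testing.assert_allclose(rev[1, 1], cmap((9 - 2) / 9)[:3])
        # multi-frame pixel: last-wins breaks the mirror symmetry
        assert not np.allclose(rev[3, 3], cmap((9 - 7) / 9)[:3])
        np.testing.assert_allclose(rev[3, 3], cmap((9 - 2) / 9)[:3])


class TestExtractTracks:
    def test_single_protrusion_exact_onset_offset(self):
        ev = sim.ProtrusionEvent(20.0, 3, 1.5, 3.0, 2, 1.5)
        cfg = sim.SceneConfig(n_frames=11, protrusion_events=[ev])
        stack, truth = sim.generate_scene(cfg)
        movie = dyn.binarize_movie(stack.channels["cytosol"], 60, cfg.pixel_size)
        tracks, nodes = dyn.extract_tracks(movie, truth.shaft_mask)
        assert len(tracks) == 1 and len(nodes) == 0
        assert (tracks[0].onset, tracks[0].offset) == (3, 7)
        np.testing.assert_allclose(
            tracks[0].lengths_um, truth.protrusions[0].lengths_um, atol=0.5
        )

    def test_bare_shaft_yields_no_tracks_or_nodes(self):
        cfg = sim.SceneConfig(n_frames=5)
        stack, truth = sim.generate_scene(cfg)
        movie = dyn.binarize_movie(stack.channels["cytosol"], 60, cfg.pixel_size)
        tracks, nodes = dyn.extract_tracks(movie, truth.shaft_mask)
        assert tracks == [] and nodes == []

    def test_node_emerging_protrusions_carry_links(self):
        cfg, stack, truth = node_scene(n_from_node=8, n_total=10)
        movie = dyn.binarize_movie(stack.channels["cytosol"], 60, cfg.pixel_size)
        tracks, nodes = dyn.extract_tracks(movie, truth.shaft_mask, link_radius_um=1.5)
        assert len(tracks) == 10
        assert len(nodes) == 8
        assert sum(t.node_id is not None for t in tracks) == 8
        # the linked tracks are exactly the planted node-emerging ones
        linked = sorted(round(t.origin[1]) for t in tracks if t.node_id is not None)
        planted = sorted(
            round(p.origin[1]) for p in truth.protrusions if p.from_node_flag
        )
        assert all(abs(a - b) <= 2 for a, b in zip(linked, planted))

    def test_empty_shaft_mask_rejected(self):
        movie = dyn.BinaryMovie(np.zeros((2, 8, 8), bool), 60, 0.2)
        with pytest.raises(ValueError):
            dyn.extract_tracks(movie, np.zeros((8, 8), bool))

    def test_shaft_mask_derivable_from_persistent_foreground(self):
        ev = sim.ProtrusionEvent(20.0, 3, 1.5, 3.0, 2, 1.5)
        cfg = sim.SceneConfig(n_frames=11, protrusion_events=[ev])
        stack, truth = sim.generate_scene(cfg)
        movie = dyn.binarize_movie(stack.channels["cytosol"], 60, cfg.pixel_size)
        derived = dyn.derive_shaft_mask(movie)
        inter = (derived & truth.shaft_mask).sum()
        union = (derived | truth.shaft_mask).sum()
        assert inter / union >= 0.9


class TestClassifyTrack:
    def test_full_span_is_static(self):
        ct = dyn.classify_track(_track(0, 10), 10, 60)
        assert ct.label == "static"

    def test_interior_three_minute_track_is_transient(self):
        # 3 frames at 60 s = 3 min, but neither boundary condition holds
        ct = dyn.classify_track(_track(3, 5), 10, 60)
        assert ct.label == "transient"
        assert ct.duration_min == pytest.approx(3.0)

    def test_late_onset_to_end_is_stabilized(self):
        ct = dyn.classify_track(_track(2, 10), 10, 60)
        assert ct.label == "stabilized"

    def test_start_to_middle_with_persistence_is_collapsed(self):
        ct = dyn.classify_track(_track(0, 4), 10, 60)
        assert ct.label == "collapsed"

    def test_persistence_is_inclusive_at_exactly_three_minutes(self):
        assert dyn.classify_track(_track(8, 10), 10, 60).label == "stabilized"
        assert dyn.classify_track(_track(9, 10), 10, 60).label == "transient"
        assert dyn.classify_track(_track(0, 2), 10, 60).label == "collapsed"
        assert dyn.classify_track(_track(0, 1), 10, 60).label == "transient"

    def test_track_outside_movie_rejected(self):
        with pytest.raises(ValueError):
            dyn.classify_track(_track(0, 11), 10, 60)

    def test_agrees_with_rule_oracle_on_random_tracks(self, rng):
        for _ in range(300):
            interval = float(rng.choice([15.0, 60.0, 120.0]))
            n_frames = int(rng.integers(3, 15))
            minutes = (n_frames - 1) * interval / 60.0
            onset = int(rng.integers(0, n_frames))
            offset = int(rng.integers(onset, n_frames))
            got = dyn.classify_track(_track(onset, offset), minutes, interval).label
            assert got == classify_oracle(onset, offset, n_frames, interval)


class TestSummary:
    def test_rate_arithmetic(self):
        classified = [
            dyn.classify_track(_track(0, 10), 10, 60) for _ in range(10)
        ] + [dyn.classify_track(_track(4, 5), 10, 60) for _ in range(5)]
        s = dyn.dynamics_summary(classified, nodes=[])
        assert s.n_static == 10 and s.n_transient == 5
        assert s.dynamic_per_static == pytest.approx(0.5)

    def test_nodes_count_toward_dynamic_events(self):
        classified = [dyn.classify_track(_track(0, 10), 10, 60) for _ in range(4)]
        nodes = [dyn.NodeEvent(1, 2, np.array([[0.0, 0.0]]))] * 2
        s = dyn.dynamics_summary(classified, nodes)
        assert s.dynamic_per_static == pytest.approx(0.5)

    def test_zero_static_marks_rate_undefined(self):
        classified = [dyn.classify_track(_track(4, 5), 10, 60)]
        s = dyn.dynamics_summary(classified, nodes=[])
        assert s.dynamic_per_static is None
        assert s.n_transient == 1

    def test_all_de_novo_linked_gives_fraction_one(self):
        tracks = [_track(2, 5, node_id=0), _track(3, 6, node_id=1)]
        assert dyn.node_emergence_fraction(tracks) == pytest.approx(1.0)

    def test_frame_zero_protrusions_excluded_from_denominator(self):
        tracks = [_track(0, 5), _track(2, 5, node_id=0), _track(3, 6)]
        assert dyn.node_emergence_fraction(tracks) == pytest.approx(0.5)

    def test_per_group_estimator_averages_over_groups(self):
        tracks = [
            _track(1, 3, node_id=0), _track(2, 4),  # group 0: 1/2
            _track(1, 3, node_id=1),                 # group 1: 1/1
        ]
        pooled = dyn.node_emergence_fraction(tracks)
        per_group = dyn.node_emergence_fraction(tracks, groups=[0, 0, 1])
        assert pooled == pytest.approx(2 / 3)
        assert per_group == pytest.approx(0.75)

    def test_density_over_proximal_stretch(self):
        # 50 µm dendrite, 3 protrusions on it: 3 / (50/10) = 0.6 per 10 µm
        path = np.array([[0.0, 10.0], [50.0, 10.0]])  # (x, y) px at 1 µm/px
        tracks = [_track(1, 3, origin=(10.0, float(x))) for x in (5, 20, 40)]
        d = dyn.filopodia_density(tracks, [path], pixel_size=1.0)
        assert d == pytest.approx(0.6)

    def test_density_ignores_distal_protrusions(self):
        path = np.array([[0.0, 10.0], [150.0, 10.0]])  # 150 µm; proximal 100 only
        tracks = [_track(1, 3, origin=(10.0, 50.0)), _track(1, 3, origin=(10.0, 140.0))]
        d = dyn.filopodia_density(tracks, [path], pixel_size=1.0)
        assert d == pytest.approx(1 / (100 / 10))


class TestIntervalSubsample:
    def test_identity_at_native_interval(self):
        tracks, nodes = sim.generate_node_protrusion_events(
            20, 0.5, movie_minutes=10, frame_interval=15, seed=0
        )
        t2, n2 = dyn.interval_subsample(tracks, nodes, 15, 15, link_radius_px=5.0)
        assert [(t.onset, t.offset) for t in t2] == [(t.onset, t.offset) for t in tracks]
        assert len(n2) == len(nodes)

    def test_node_between_retained_frames_is_lost(self):
        node = dyn.NodeEvent(5, 7, np.zeros((3, 2)), node_id=0)
        track = _track(9, 20, origin=(0.0, 0.0))
        t2, n2 = dyn.interval_subsample([track], [node], 15, 60, link_radius_px=5.0)
        assert n2 == []
        assert t2[0].node_id is None

    def test_non_multiple_target_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            dyn.interval_subsample([], [], 15, 40, link_radius_px=5.0)

    def test_coarser_sampling_never_increases_node_fraction(self):
        for seed in range(10):
            tracks, nodes = sim.generate_node_protrusion_events(
                40, 0.8, movie_minutes=10, frame_interval=15, seed=seed
            )
            lr = 1.0 / 0.2
            t15, _ = dyn.interval_subsample(tracks, nodes, 15, 15, lr)
            t60, _ = dyn.interval_subsample(tracks, nodes, 15, 60, lr)
            f15 = dyn.node_emergence_fraction(t15)
            f60 = dyn.node_emergence_fraction(t60)
            assert f60 <= f15

    def test_estimator_consistency_with_sample_size(self):
        # absolute error vs the planted fraction shrinks from n=50 to n=500
        errs = {50: [], 500: []}
        for n in errs:
            for seed in range(20):
                tracks, nodes = sim.generate_node_protrusion_events(
                    n, 0.83, movie_minutes=10, frame_interval=15, seed=seed
                )
                f = dyn.node_emergence_fraction(tracks)
                errs[n].append(abs(f - 0.83))
        assert np.mean(errs[500]) <= np.mean(errs[50])
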