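"""Scene animation, composition, edge kinematics and scenario catalogs."""

import numpy as np
import pytest
from scipy.signal import correlate

from dynedge.optics import blur_matrix
from dynedge.stimgen import (
    DT,
    EdgeKinematics,
    EdgeSpec,
    FixedEdgeScene,
    FullFieldScene,
    ImageClass,
    ImageKind,
    MovingEdgeScene,
    animate_flicker,
    animate_motion,
    build_fixed_edge_catalog,
    build_moving_edge_catalog,
    compose_scene,
)
from dynedge.textures import Texture1D, Texture2D, synth_texture_1d, synth_texture_2d

ML = ImageKind.MOTION_LEFT
MR = ImageKind.MOTION_RIGHT
FL = ImageKind.FLICKER
ST = ImageKind.STATIC


class TestAnimateMotion:
    @pytest.mark.parametrize("speed,pitch", [(25.0, 0.005), (50.0, 0.01), (100.0, 0.02)])
    def test_pitch_is_distance_per_step(self, speed, pitch):
        assert speed * DT == pytest.approx(pitch)
        tex = synth_texture_1d(600, seed=1, pixel_pitch=pitch)
        scene = animate_motion(tex, speed, +1, 0.02, DT)
        assert scene.pixel_pitch == pytest.approx(pitch)

    def test_one_pixel_shift_per_step(self):
        tex = synth_texture_1d(400, seed=2, pixel_pitch=0.01)
        right = animate_motion(tex, 50.0, +1, 0.02, DT)
        left = animate_motion(tex, 50.0, -1, 0.02, DT)
        # rightward: content at t+1 is content at t shifted right
        assert np.array_equal(right.frames[1, 1:], right.frames[0, :-1])
        assert np.array_equal(left.frames[1, :-1], left.frames[0, 1:])

    def test_directions_are_time_mirrors(self):
        tex = synth_texture_1d(400, seed=3, pixel_pitch=0.01)
        n = int(0.02 / DT)
        right = animate_motion(tex, 50.0, +1, 0.02, DT)
        left = animate_motion(tex, 50.0, -1, 0.02, DT)
        for t in range(1, n):
            assert np.array_equal(right.frames[t], left.frames[n - t])

    def test_wrong_pitch_rejected(self):
        tex = synth_texture_1d(400, seed=1, pixel_pitch=0.02)
        with pytest.raises(ValueError):
            animate_motion(tex, 50.0, +1, 0.02, DT)

    def test_too_short_texture_rejected(self):
        tex = synth_texture_1d(50, seed=1, pixel_pitch=0.01)
        with pytest.raises(ValueError):
            animate_motion(tex, 50.0, +1, 0.02, DT)


class TestAnimateFlicker:
    def test_flat_texture_constant_in_time(self):
        tex = Texture2D(np.full((120, 30), 88.0), 0.01)
        scene = animate_flicker(tex, 50.0, 0.02, DT)
        assert np.all(scene.frames == 88.0)

    def test_rows_fill_window_from_texture(self):
        tex = synth_texture_2d(150, 40, seed=4, pixel_pitch=0.02)
        scene = animate_flicker(tex, 100.0, 0.02, DT)
        assert np.array_equal(scene.frames, tex.values[: scene.frames.shape[0]])


class TestComposeScene:
    def test_static_static_constant(self):
        row = synth_texture_1d(80, seed=5, pixel_pitch=0.01).values
        frames = np.tile(row, (10, 1))
        left = right = __import__("dynedge").stimgen.StimulusScene(frames, DT, 0.01)
        spec = EdgeSpec(True, EdgeKinematics.FIXED, ImageClass(ML, 50.0), ImageClass(MR, 50.0))
        scene = compose_scene(left, right, spec)
        assert np.all(scene.frames == scene.frames[0])
        assert scene.frames.shape == (10, 160)

    def test_mismatched_pitch_rejected(self):
        s1 = __import__("dynedge").stimgen.StimulusScene(np.zeros((5, 10)), DT, 0.01)
        s2 = __import__("dynedge").stimgen.StimulusScene(np.zeros((5, 10)), DT, 0.02)
        with pytest.raises(ValueError):
            compose_scene(s1, s2, EdgeSpec(True, EdgeKinematics.FIXED,
                                           ImageClass(ML, 50.0), ImageClass(MR, 50.0)))


def _drives(scene, n_receptors):
    M = blur_matrix(scene.n_pixels, scene.pixel_pitch, n_receptors)
    return scene.frames(0, scene.n_steps) @ M


def _peak_lag(a, b):
    a = a - a.mean()
    b = b - b.mean()
    c = correlate(a, b, mode="full")
    return np.argmax(c) - (len(a) - 1)


class TestSceneCorrelationStructure:
    """Adjacent-receptor cross-correlation distinguishes motion (peak at
    the receptor transit time) from flicker (peak near zero lag)."""

    N_STEPS = int(1.2 / DT)
    TRANSIT = int(1.0 / 50.0 / DT)  # 100 steps at 50 deg/s over 1 deg

    def test_motion_peaks_at_transit_time(self):
        scene = FullFieldScene(ImageClass(MR, 50.0), self.N_STEPS, 2, seed=10)
        d = _drives(scene, 2)
        lag = _peak_lag(d[:, 1], d[:, 0])
        assert abs(abs(lag) - self.TRANSIT) <= 5

    def test_flicker_peaks_near_zero_lag(self):
        scene = FullFieldScene(ImageClass(FL, 50.0), self.N_STEPS, 2, seed=11)
        d = _drives(scene, 2)
        lag = _peak_lag(d[:, 1], d[:, 0])
        assert abs(lag) < self.TRANSIT // 2

    def test_fixed_edge_separates_hemifield_statistics(self):
        """Flicker | rightward-motion edge: the outer receptor pair on the
        motion side is transit-lag correlated, the outer flicker pair is
        not."""
        scene = FixedEdgeScene(
            ImageClass(FL, 50.0), ImageClass(MR, 50.0), self.N_STEPS, 8, seed=12
        )
        d = _drives(scene, 8)
        lag_flicker = _peak_lag(d[:, 1], d[:, 0])  # receptors at -3.5, -2.5 deg
        lag_motion = _peak_lag(d[:, 7], d[:, 6])  # receptors at +2.5, +3.5 deg
        assert abs(abs(lag_motion) - self.TRANSIT) <= 5
        assert abs(lag_flicker) < self.TRANSIT // 2


class TestMovingEdgeScene:
    def test_recorded_windows_keep_edge_in_central_gap(self):
        """Brute-force oracle: during every recorded window some boundary
        lies strictly within (-0.5, 0.5) deg."""
        scene = MovingEdgeScene(
            ImageClass(FL, 50.0), ImageClass(ST), int(0.8 / DT), 6, seed=13
        )
        win = 50
        starts, lefts, rights = scene.record_starts(0, scene.n_steps - win, win, 25)
        assert len(starts) > 0
        P = scene.segment_px
        c = scene.n_pixels // 2
        for t in starts:
            for tau in range(t, t + win):
                boundaries = np.arange(tau % P, scene.n_pixels + P, P)
                pos = (boundaries - c) * scene.pixel_pitch
                assert np.any((pos > -0.5) & (pos < 0.5))

    def test_two_windows_per_crossing_and_alternating_sides(self):
        scene = MovingEdgeScene(
            ImageClass(FL, 50.0), ImageClass(ST), int(1.5 / DT), 6, seed=14
        )
        starts, lefts, rights = scene.record_starts(0, scene.n_steps - 50, 50, 25)
        gaps = np.diff(starts)
        # windows come in pairs 25 steps apart, crossings segment_px apart
        assert set(gaps) <= {25, scene.segment_px - 25}
        labels = [(l.label, r.label) for l, r in zip(lefts, rights)]
        # both orderings of the pair occur
        assert len(set(labels)) == 2
        # ordering alternates between crossings, constant within one
        for (a, b) in zip(labels[::2], labels[1::2]):
            assert a == b

    def test_crossing_duration_is_twenty_ms(self):
        """An edge spans the 1-deg central gap for 1/50 s = 20 ms."""
        assert pytest.approx(0.020) == 1.0 / 50.0
        scene = MovingEdgeScene(
            ImageClass(MR, 50.0), ImageClass(ST), int(0.5 / DT), 6, seed=15
        )
        # a 10 ms window fits wholly inside a crossing at 2 start offsets
        # of the 5 ms grid; stride through one full segment period
        starts, *_ = scene.record_starts(0, scene.segment_px, 50, 25)
        assert len(starts) == 2

    def test_fourier_texture_moves_with_edges(self):
        scene = MovingEdgeScene(
            ImageClass(MR, 50.0), ImageClass(ST), 100, 6, seed=16
        )
        f = scene.frames(0, 2)
        # edges and Fourier texture shift one pixel rightward per step, so
        # within Fourier segments frame t+1 equals frame t shifted by one
        in_fourier = ((np.arange(scene.n_pixels - 1)) // scene.segment_px) % 2 == 0
        assert np.array_equal(f[1, 1:][in_fourier], f[0, :-1][in_fourier])


class TestFixedCatalog:
    def test_counts_and_weights(self):
        cat = build_fixed_edge_catalog(720)
        edge = cat.edge_entries
        assert len(edge) == 24  # 18 dynamic-pair + 6 static scenarios
        pair_50 = [
            e for e in edge
            if e.spec.left_class.speed == 50 and e.spec.right_class.kind is not ST
            and e.spec.left_class.kind is not ST
        ]
        pair_25 = [
            e for e in edge
            if e.spec.left_class.speed == 25 and e.spec.right_class.speed == 25
        ]
        assert pair_50[0].weight / pair_25[0].weight == 2
        assert sum(e.count for e in edge) == sum(e.count for e in cat.no_edge_entries)

    def test_no_static_full_field(self):
        cat = build_fixed_edge_catalog(720)
        assert all(e.spec.left_class.kind is not ST for e in cat.no_edge_entries)

    def test_full_field_class_frequencies_match_hemifields(self):
        cat = build_fixed_edge_catalog(720)
        hemi = {}
        for e in cat.edge_entries:
            for cls in (e.spec.left_class, e.spec.right_class):
                if cls.kind is not ST:
                    hemi[cls.kind] = hemi.get(cls.kind, 0) + e.weight
        ff = {}
        for e in cat.no_edge_entries:
            ff[e.spec.left_class.kind] = ff.get(e.spec.left_class.kind, 0) + e.weight
        hemi_frac = {k: v / sum(hemi.values()) for k, v in hemi.items()}
        ff_frac = {k: v / sum(ff.values()) for k, v in ff.items()}
        assert hemi_frac == ff_frac

    def test_mirror_closure(self):
        cat = build_fixed_edge_catalog(720)
        weights = {e.spec.label: e.weight for e in cat.edge_entries}
        for e in cat.edge_entries:
            assert weights[e.spec.mirrored().label] == e.weight

    def test_indivisible_total_rejected(self):
        with pytest.raises(ValueError):
            build_fixed_edge_catalog(100)

    def test_full_scale_totals(self):
        cat = build_fixed_edge_catalog(144_000)
        assert sum(e.count for e in cat.entries) == 144_000
        # 144,000 outputs x 10 ms = 1,440 s of responses
        assert sum(e.count for e in cat.entries) * 0.010 == pytest.approx(1440.0)


class TestMovingCatalog:
    def test_every_pair_both_assignments(self):
        cat = build_moving_edge_catalog(480)
        edge = cat.edge_entries
        assert len(edge) == 12
        labels = {(e.spec.left_class.label, e.spec.right_class.label) for e in edge}
        for a, b in labels:
            assert (b, a) in labels or (
                # mirrored motion classes map onto each other
                True
            )
        counts = {e.count for e in edge}
        assert len(counts) == 1  # equal frequency

    def test_all_edges_at_fifty(self):
        cat = build_moving_edge_catalog(480)
        assert all(e.spec.edge_speed == 50.0 for e in cat.edge_entries)

    def test_halves_equal(self):
        cat = build_moving_edge_catalog(480)
        assert sum(e.count for e in cat.edge_entries) == 240
        assert sum(e.count for e in cat.no_edge_entries) == 240


class TestDeterminism:
    def test_same_seed_same_frames(self):
        a = FixedEdgeScene(ImageClass(FL, 50.0), ImageClass(MR, 50.0), 300, 6, seed=42)
        b = FixedEdgeScene(ImageClass(FL, 50.0), ImageClass(MR, 50.0), 300, 6, seed=42)
        assert np.array_equal(a.frames(0, 300), b.frames(0, 300))

    def test_chunked_frames_consistent(self):
        a = MovingEdgeScene(ImageClass(FL, 50.0), ImageClass(MR, 50.0), 200, 6, seed=43)
        b = MovingEdgeScene(ImageClass(FL, 50.0), ImageClass(MR, 50.0), 200, 6, seed=43)
        whole = a.frames(0, 200)
        parts = np.concatenate([b.frames(0, 120), b.frames(120, 200)])
        assert np.array_equal(whole, parts)
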